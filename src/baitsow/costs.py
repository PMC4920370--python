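"""Farm-plan cost model: control frequency -> per-hectare and farm costs.

Given how often repeat control is needed (the mean years-to-recovery from
the simulator, used as the interval between operations), the cost of one
operation per hectare, and a management horizon, the model prices a control
schedule pro-rata: fractional operation counts are retained so cost accrues
continuously, i.e. cost per ha per year = cost per operation / frequency
identically, independent of the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .recovery import RecoverySummary

__all__ = [
    "CostParams",
    "CostResult",
    "cost_schedule",
    "farm_saving",
    "scenario_table",
    "SCENARIOS",
]

#: Fixed scenario order: growth regime (pre/post an RHD epidemic) x sowing
#: pattern.
SCENARIOS = (
    "pre_rhd_strip",
    "pre_rhd_broadcast",
    "post_rhd_strip",
    "post_rhd_broadcast",
)


@dataclass(frozen=True)
class CostParams:
    """Per-operation costs by treatment ($NZ/ha), horizon and farm area."""

    cost_per_op: Mapping[str, float] = field(
        default_factory=lambda: {"strip": 75.0, "broadcast": 100.0}
    )
    horizon: float = 20.0
    farm_area: float = 2000.0

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.farm_area <= 0:
            raise ValueError("horizon and farm area must be positive")
        if any(v <= 0 for v in self.cost_per_op.values()):
            raise ValueError("costs must be positive")


@dataclass(frozen=True)
class CostResult:
    """Cost of one control schedule over a management horizon (per ha)."""

    frequency: float
    cost_per_op: float
    horizon: float
    n_ops: float
    cost_per_ha_horizon: float
    cost_per_ha_year: float

    @classmethod
    def from_horizon_cost(
        cls, cost_per_ha_horizon: float, cost_per_op: float, horizon: float = 20.0
    ) -> "CostResult":
        """Reconstruct a schedule from its total per-ha cost over the horizon."""
        if cost_per_ha_horizon <= 0:
            raise ValueError("horizon cost must be positive")
        n_ops = cost_per_ha_horizon / cost_per_op
        return cls(
            frequency=horizon / n_ops,
            cost_per_op=cost_per_op,
            horizon=horizon,
            n_ops=n_ops,
            cost_per_ha_horizon=cost_per_ha_horizon,
            cost_per_ha_year=cost_per_ha_horizon / horizon,
        )


def cost_schedule(frequency: float, cost_per_op: float, horizon: float = 20.0) -> CostResult:
    """Price a schedule of one operation every ``frequency`` years.

    Fractional operation counts are allowed: n_ops = horizon/frequency.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if cost_per_op <= 0 or horizon <= 0:
        raise ValueError("cost and horizon must be positive")
    n_ops = horizon / frequency
    total = n_ops * cost_per_op
    return CostResult(
        frequency=frequency,
        cost_per_op=cost_per_op,
        horizon=horizon,
        n_ops=n_ops,
        cost_per_ha_horizon=total,
        cost_per_ha_year=total / horizon,
    )


def farm_saving(
    strip: CostResult, broadcast: CostResult, farm_area: float, per: str = "horizon"
) -> float:
    """Whole-farm saving of strip- over broadcast-sowing, $NZ.

    ``per="horizon"`` gives the saving over the full management horizon,
    ``per="year"`` the annualized saving (horizon saving / horizon years).
    """
    if strip.horizon != broadcast.horizon:
        raise ValueError("mismatched horizons")
    if per not in ("horizon", "year"):
        raise ValueError(f"unknown per={per!r}")
    diff = (broadcast.cost_per_ha_horizon - strip.cost_per_ha_horizon) * farm_area
    if per == "year":
        return diff / strip.horizon
    return diff


def scenario_table(recovery: Mapping[str, "RecoverySummary | float"], costs: CostParams) -> pd.DataFrame:
    """Cost table over the four growth x treatment scenarios.

    ``recovery`` maps each scenario in :data:`SCENARIOS` to a
    :class:`~baitsow.recovery.RecoverySummary` (its mean years-to-recovery is
    used as the operation frequency) or directly to a frequency in years.
    """
    missing = [s for s in SCENARIOS if s not in recovery]
    if missing:
        raise ValueError(f"missing scenario(s): {missing}")
    rows = []
    for scen in SCENARIOS:
        val = recovery[scen]
        freq = val.mean_years if isinstance(val, RecoverySummary) else float(val)
        regime, treatment = scen.rsplit("_", 1)
        res = cost_schedule(freq, costs.cost_per_op[treatment], costs.horizon)
        rows.append(
            {
                "scenario": scen,
                "growth_regime": regime,
                "treatment": treatment,
                "frequency_years": res.frequency,
                "cost_per_ha_per_op": res.cost_per_op,
                "n_ops_horizon": res.n_ops,
                "cost_per_ha_horizon": res.cost_per_ha_horizon,
                "cost_per_ha_year": res.cost_per_ha_year,
            }
        )
    return pd.DataFrame(rows)
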