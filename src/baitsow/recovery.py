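"""Monte-Carlo simulation of rabbit population recovery after control.

The population index is normalized so that carrying capacity K equals the
pre-control density.  A control operation applied on a fixed calendar day
removes a beta-distributed fraction of the population (the operation's
percentage kill); the survivors then grow back along a density-dependent
logistic trajectory with instantaneous rate of increase r, optionally
concentrated into a seasonal breeding window.  Each Monte-Carlo run records
the number of years until the index again reaches a threshold fraction q of
the pre-control density ("recovered"); the distribution of those times sets
how often repeat control is needed, which the cost module prices.

Under pure logistic growth the pre-control density is approached only
asymptotically, so "recovery" needs a threshold; the default is q = 0.95 and
the sensitivity to q should always be examined (the CLI ``simulate
--q-sensitivity`` flag prints it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "BreedingSeason",
    "GrowthParams",
    "KillDistribution",
    "FixedKill",
    "SimConfig",
    "RecoverySummary",
    "RecoveryModel",
    "beta_from_moments",
    "simulate_trajectory",
    "recovery_time_closed_form",
    "monte_carlo_recovery",
]

DAYS_PER_YEAR = 365.0
JULY_1 = 182  # day-of-year of the default control date (non-leap)


@dataclass(frozen=True)
class BreedingSeason:
    """Breeding window as inclusive day-of-year bounds (may wrap the year end).

    Growth is zero outside the window and rescaled inside it so that the
    integral of the effective rate over a year still equals the annual r.
    """

    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        for d in (self.start_day, self.end_day):
            if not 1 <= d <= 365:
                raise ValueError("season days must lie in 1..365")

    @property
    def length_days(self) -> int:
        if self.start_day <= self.end_day:
            return self.end_day - self.start_day + 1
        return 365 - self.start_day + 1 + self.end_day

    def mask(self) -> np.ndarray:
        """Boolean in-window indicator indexed by day-of-year - 1."""
        days = np.arange(1, 366)
        if self.start_day <= self.end_day:
            return (days >= self.start_day) & (days <= self.end_day)
        return (days >= self.start_day) | (days <= self.end_day)


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth: instantaneous annual rate r and carrying capacity K.

    K defaults to 1.0, i.e. densities are fractions of the pre-control level.
    """

    r: float
    K: float = 1.0
    season: BreedingSeason | None = None

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")

    def r_daily(self) -> np.ndarray:
        """Effective annual-scale rate for each day of the year (length 365)."""
        if self.season is None:
            return np.full(365, self.r)
        m = self.season.mask()
        out = np.zeros(365)
        out[m] = self.r * 365.0 / self.season.length_days
        return out


@dataclass(frozen=True)
class KillDistribution:
    """Beta law for control efficacy (kill fraction in (0, 1))."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def var(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s**2 * (s + 1.0))

    @classmethod
    def from_moments(cls, mean_kill: float, var_kill: float) -> "KillDistribution":
        return beta_from_moments(mean_kill, var_kill)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class FixedKill:
    """Degenerate efficacy law: every operation kills exactly ``kill``.

    Used as the analytic-oracle counterpart of :class:`KillDistribution`.
    """

    kill: float

    def __post_init__(self) -> None:
        if not 0 < self.kill < 1:
            raise ValueError("kill must lie in (0, 1)")

    @property
    def mean(self) -> float:
        return self.kill

    @property
    def var(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.kill)


KillLaw = Union[KillDistribution, FixedKill]


def beta_from_moments(mean_kill: float, var_kill: float) -> KillDistribution:
    """Method-of-moments beta parameters from a kill mean and variance.

    alpha = m*(m(1-m)/v - 1), beta = (1-m)*(m(1-m)/v - 1); requires
    0 < v < m(1-m), otherwise no beta law has those moments.
    """
    m, v = float(mean_kill), float(var_kill)
    if not 0 < m < 1:
        raise ValueError("mean kill must lie in (0, 1)")
    if v <= 0:
        raise ValueError("variance must be positive (use FixedKill for a point mass)")
    if v >= m * (1 - m):
        raise ValueError("overdispersed for beta: need var < mean*(1-mean)")
    c = m * (1 - m) / v - 1.0
    return KillDistribution(alpha=m * c, beta=(1 - m) * c)


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo settings for the recovery simulator.

    ``recovery_threshold`` is the fraction q of pre-control density at which
    a run counts as recovered; ``control_day`` is the day-of-year of the
    operation (default 1 July), which only matters with a breeding season.
    """

    n_runs: int = 10_000
    control_day: int = JULY_1
    recovery_threshold: float = 0.95
    max_horizon: float = 100.0
    time_step_days: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.recovery_threshold < 1:
            raise ValueError("recovery threshold must lie in (0, 1)")
        if self.time_step_days <= 0:
            raise ValueError("time step must be positive")
        if not 1 <= self.control_day <= 365:
            raise ValueError("control_day must lie in 1..365")
        if self.max_horizon <= 0:
            raise ValueError("max_horizon must be positive")


@dataclass
class RecoverySummary:
    """Distribution of years-to-recovery over Monte-Carlo runs.

    Statistics are over recovered runs only; runs still below the threshold
    at the horizon are counted in ``runs_not_recovered``.
    """

    mean_years: float
    sd_years: float
    q025: float
    median: float
    q975: float
    runs_not_recovered: int
    n_runs: int
    times: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "mean_years": self.mean_years,
            "sd_years": self.sd_years,
            "q025": self.q025,
            "median": self.median,
            "q975": self.q975,
            "runs_not_recovered": self.runs_not_recovered,
            "n_runs": self.n_runs,
        }


def _step_factors(gp: GrowthParams, control_day: int, n_steps: int, dt_days: float) -> np.ndarray:
    """Per-step effective rate (annual units), piecewise constant by day."""
    r_day = gp.r_daily()
    starts = (control_day - 1 + np.floor(np.arange(n_steps) * dt_days).astype(int)) % 365
    return r_day[starts]


def simulate_trajectory(
    gp: GrowthParams,
    start_density: float,
    years: float,
    time_step_days: float = 1.0,
    method: str = "exact",
    start_day: int = JULY_1,
) -> tuple[np.ndarray, np.ndarray]:
    """Density trajectory of the logistic model from ``start_density``.

    ``method="exact"`` advances each step with the closed-form logistic flow
    (exact for piecewise-constant r); ``method="euler"`` uses the explicit
    first-order update dN = r*N*(1 - N/K)*dt and is provided for
    discretization-error checks.  Returns (times in years, densities).
    """
    if time_step_days <= 0:
        raise ValueError("time step must be positive")
    if not 0 < start_density <= gp.K:
        raise ValueError("start density must lie in (0, K]")
    if method not in ("exact", "euler"):
        raise ValueError(f"unknown method {method!r}")
    dt = time_step_days / DAYS_PER_YEAR
    n_steps = int(np.ceil(years / dt))
    if method == "euler" and gp.r * dt >= 1:
        raise ValueError("r*dt must be < 1 for the Euler update")
    r_eff = _step_factors(gp, start_day, n_steps, time_step_days)
    N = np.empty(n_steps + 1)
    N[0] = start_density
    K = gp.K
    for i in range(n_steps):
        n = N[i]
        if method == "exact":
            f = np.exp(-r_eff[i] * dt)
            N[i + 1] = K * n / (n + (K - n) * f)
        else:
            N[i + 1] = n + r_eff[i] * n * (1 - n / K) * dt
    t = np.arange(n_steps + 1) * dt
    return t, N


def recovery_time_closed_form(gp: GrowthParams, survivor_fraction: float, threshold: float) -> float:
    """Exact logistic time from density s*K to q*K: (1/r)*ln[q(1-s)/(s(1-q))].

    Returns 0 when the survivors already exceed the threshold.  Only defined
    for non-seasonal growth.
    """
    if gp.season is not None:
        raise ValueError("closed form requires non-seasonal growth")
    s, q = float(survivor_fraction), float(threshold)
    if not 0 < s <= 1:
        raise ValueError("survivor fraction must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if s >= q:
        return 0.0
    return float(np.log(q * (1 - s) / (s * (1 - q))) / gp.r)


def monte_carlo_recovery(
    gp: GrowthParams,
    kd: KillLaw,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> RecoverySummary:
    """Monte-Carlo years-to-recovery after a single control operation.

    Each run draws a kill from ``kd``, starts the survivors at K*(1-kill) on
    the control day, advances the logistic model day by day, and records the
    first time the density reaches q*K (with within-step interpolation of
    the crossing, so recovery times are not quantized to the step).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    kills = kd.sample(rng, cfg.n_runs)
    K = gp.K
    q_level = cfg.recovery_threshold * K
    N = K * (1.0 - kills)
    times = np.full(cfg.n_runs, np.nan)
    times[N >= q_level] = 0.0
    active = N < q_level

    dt_days = cfg.time_step_days
    dt = dt_days / DAYS_PER_YEAR
    n_steps = int(np.ceil(cfg.max_horizon / dt))
    r_eff = _step_factors(gp, cfg.control_day, n_steps, dt_days)
    for i in range(n_steps):
        if not active.any():
            break
        r = r_eff[i]
        if r == 0.0:
            continue
        f = np.exp(-r * dt)
        n_old = N[active]
        n_new = K * n_old / (n_old + (K - n_old) * f)
        crossed = n_new >= q_level
        if crossed.any():
            n_c = n_old[crossed]
            # exact within-step crossing time of the logistic flow
            frac = np.log(q_level * (K - n_c) / (n_c * (K - q_level))) / r
            idx = np.flatnonzero(active)
            times[idx[crossed]] = i * dt + frac
            still = idx[~crossed]
            N[still] = n_new[~crossed]
            active[:] = False
            active[still] = True
        else:
            N[active] = n_new

    not_rec = int(np.isnan(times).sum())
    if not_rec:
        warnings.warn(
            f"{not_rec} of {cfg.n_runs} runs had not recovered within "
            f"{cfg.max_horizon} years; excluded from summary statistics",
            stacklevel=2,
        )
    rec = times[~np.isnan(times)]
    if rec.size == 0:
        return RecoverySummary(
            np.nan, np.nan, np.nan, np.nan, np.nan, not_rec, cfg.n_runs, times
        )
    q025, med, q975 = np.percentile(rec, [2.5, 50.0, 97.5])
    sd = float(rec.std(ddof=1)) if rec.size > 1 else 0.0
    return RecoverySummary(
        mean_years=float(rec.mean()),
        sd_years=sd,
        q025=float(q025),
        median=float(med),
        q975=float(q975),
        runs_not_recovered=not_rec,
        n_runs=cfg.n_runs,
        times=times,
    )


class RecoveryModel:
    """Population-recovery simulator: growth law + efficacy law + settings.

    Thin object facade over :func:`monte_carlo_recovery`;
    ``RecoveryModel(gp, kd, cfg).simulate()`` returns a
    :class:`RecoverySummary`.
    """

    def __init__(self, growth: GrowthParams, kill: KillLaw, config: SimConfig | None = None):
        self.growth = growth
        self.kill = kill
        self.config = config or SimConfig()

    def simulate(self, seed: int | None = None) -> RecoverySummary:
        cfg = self.config
        if seed is not None:
            cfg = SimConfig(
                n_runs=cfg.n_runs,
                control_day=cfg.control_day,
                recovery_threshold=cfg.recovery_threshold,
                max_horizon=cfg.max_horizon,
                time_step_days=cfg.time_step_days,
                seed=seed,
            )
        return monte_carlo_recovery(self.growth, self.kill, cfg)
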