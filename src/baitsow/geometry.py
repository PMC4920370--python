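"""Aerial bait-sowing geometry: coverage, density, gaps and toxin loading.

A sowing plan is described by the flight-path spacing (FPS, distance between
successive flight lines), the baited swath width each pass deposits, the
sowing rate averaged over the whole treated block (kg/ha including any
unbaited gaps), the toxin mass fraction of the bait, and the mean bait mass.
Broadcast sowing has swath = FPS (complete coverage); strip-sowing leaves
unbaited gaps of width FPS - swath between strips and concentrates the same
per-pass bait into a narrow band, raising the within-strip density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SowingPlan",
    "StripDensity",
    "BaitMassBins",
    "area_fraction_baited",
    "gap_width",
    "within_strip_density",
    "toxin_per_ha",
    "mass_bins",
    "STRIP_OTAGO",
    "BROADCAST_OTAGO",
]

M2_PER_HA = 10_000.0
G_PER_KG = 1_000.0


@dataclass(frozen=True)
class SowingPlan:
    """Geometry and loading of one aerial baiting treatment.

    Parameters
    ----------
    pattern : {"strip", "broadcast"}
    sowing_rate : float
        kg of bait per hectare, averaged over the whole block.
    fps : float
        Flight-path spacing, m.
    swath : float
        Baited swath width per pass, m.  Must equal ``fps`` for broadcast.
    toxin_conc : float
        Toxin mass fraction of the bait (0.0002 for 0.02% wt/wt).
    mean_bait_mass : float
        Mean mass of an individual bait, g.
    """

    pattern: str
    sowing_rate: float
    fps: float
    swath: float
    toxin_conc: float = 0.0002
    mean_bait_mass: float = 6.0

    def __post_init__(self) -> None:
        if self.pattern not in ("strip", "broadcast"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.fps <= 0:
            raise ValueError("flight-path spacing must be positive")
        if not 0 < self.swath <= self.fps:
            raise ValueError("swath must satisfy 0 < swath <= fps")
        if self.pattern == "broadcast" and self.swath != self.fps:
            raise ValueError("broadcast requires swath == fps (full coverage)")
        if self.sowing_rate <= 0:
            raise ValueError("sowing rate must be positive")
        if not 0 < self.toxin_conc < 1:
            raise ValueError("toxin concentration must be a fraction in (0, 1)")

    # Derived quantities are also exposed as module-level functions below.
    @property
    def area_fraction_baited(self) -> float:
        return min(self.swath / self.fps, 1.0)

    @property
    def gap_width(self) -> float:
        return self.fps - self.swath

    @property
    def toxin_per_ha(self) -> float:
        return self.sowing_rate * G_PER_KG * self.toxin_conc

    def within_strip_density(self) -> "StripDensity":
        if self.mean_bait_mass <= 0:
            raise ValueError("mean bait mass must be positive")
        g_per_m2_overall = self.sowing_rate * G_PER_KG / M2_PER_HA
        g_per_m2 = g_per_m2_overall / self.area_fraction_baited
        return StripDensity(
            g_per_m2=g_per_m2, baits_per_m2=g_per_m2 / self.mean_bait_mass
        )

    def describe(self) -> str:
        d = self.within_strip_density()
        lines = [
            f"pattern:                {self.pattern}",
            f"sowing rate:            {self.sowing_rate:g} kg/ha",
            f"flight-path spacing:    {self.fps:g} m",
            f"swath width:            {self.swath:g} m",
            f"area fraction baited:   {self.area_fraction_baited:.4f}",
            f"unbaited gap:           {self.gap_width:g} m",
            f"within-strip density:   {d.g_per_m2:.3f} g/m^2 "
            f"= {d.baits_per_m2:.3f} baits/m^2 at {self.mean_bait_mass:g} g/bait",
            f"toxin applied:          {self.toxin_per_ha:.3f} g/ha "
            f"({100 * self.toxin_conc:g}% wt/wt)",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class StripDensity:
    """Bait density inside the baited swaths."""

    g_per_m2: float
    baits_per_m2: float


@dataclass(frozen=True)
class BaitMassBins:
    """Fractions of collected baits in the <4 g, 4-6 g and >6 g mass classes."""

    fractions: tuple[float, float, float]
    n_baits: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def area_fraction_baited(plan: SowingPlan) -> float:
    """Fraction of the block covered by bait, swath/fps (capped at 1)."""
    return plan.area_fraction_baited


def gap_width(plan: SowingPlan) -> float:
    """Unbaited gap between adjacent swaths, fps - swath (m)."""
    return plan.gap_width


def within_strip_density(plan: SowingPlan) -> StripDensity:
    """Bait density inside the baited swaths (g/m^2 and baits/m^2).

    The whole-block sowing rate is concentrated into the baited fraction;
    bait count density assumes the given mean bait mass.
    """
    return plan.within_strip_density()


def toxin_per_ha(plan: SowingPlan) -> float:
    """Grams of active toxin applied per treated hectare."""
    return plan.toxin_per_ha


def mass_bins(bait_masses: Sequence[float]) -> BaitMassBins:
    """Classify bait masses into <4 g, 4-6 g (closed) and >6 g fractions."""
    m = np.asarray(list(bait_masses), dtype=float)
    if m.size == 0:
        raise ValueError("no bait masses")
    if np.any(m <= 0):
        raise ValueError("bait masses must be positive")
    low = float(np.mean(m < 4.0))
    high = float(np.mean(m > 6.0))
    mid = 1.0 - low - high
    return BaitMassBins(fractions=(low, mid, high), n_baits=int(m.size))


#: Central Otago trial defaults: 10 kg/ha in 10 m strips every 75 m vs
#: 30 kg/ha broadcast (25 m swath = 25 m FPS), 0.02% wt/wt 1080 on 6 g carrot.
STRIP_OTAGO = SowingPlan("strip", sowing_rate=10.0, fps=75.0, swath=10.0)
BROADCAST_OTAGO = SowingPlan("broadcast", sowing_rate=30.0, fps=25.0, swath=25.0)
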