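"""Kill-rate statistics for spotlight-count bait-sowing trials.

Each treatment block (replicate) is monitored with four 800 m spotlight
transects, counted on two consecutive nights before and again after an aerial
1080 operation.  The replicate abundance index is the mean count per transect;
the percentage kill is the relative drop in that index from pre- to
post-control.  This module turns a raw transect-count table into

* per-replicate kill estimates (:func:`replicate_index`, :func:`percent_kill`),
* treatment-level means with Student-t confidence intervals
  (:func:`treatment_summary`), a replicate-weighted pooled mean
  (:func:`combined_mean`) and a Welch two-sample comparison (:func:`welch_t`),
* an ANCOVA of log survivors on log initial counts with a treatment
  interaction (:func:`survivor_model`), asking whether more rabbits survive
  where more were present initially,
* a boundary-adjusted logit transform for kill proportions
  (:func:`logit_adjusted`).

The :class:`TrialEfficacy` model class wraps the whole analysis in a
statsmodels-like construct-then-``fit()`` interface.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TREATMENTS",
    "PERIODS",
    "TransectCount",
    "ReplicateResult",
    "TreatmentSummary",
    "WelchResult",
    "SurvivorModelFit",
    "TrialEfficacy",
    "TrialEfficacyResults",
    "replicate_index",
    "percent_kill",
    "treatment_summary",
    "combined_mean",
    "welch_t",
    "logit_adjusted",
    "survivor_model",
    "counts_to_frame",
    "validate_counts",
]

TREATMENTS = ("strip", "broadcast")
PERIODS = ("pre", "post")

#: Half of the smallest possible nonzero replicate index (1 rabbit on one of
#: 4 transects x 2 nights = 1/8); added to zero post-control indices so the
#: log transform in the survivor ANCOVA stays defined.
DEFAULT_ZERO_ADJUST = 0.5 / 8


@dataclass(frozen=True)
class TransectCount:
    """One spotlight count: one transect, one night, pre or post control."""

    block_id: str
    treatment: str
    transect_id: int
    night: int
    period: str
    count: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class ReplicateResult:
    """Pre/post abundance indices and percentage kill for one block."""

    block_id: str
    treatment: str
    pre_index: float
    post_index: float
    percent_kill: float


@dataclass(frozen=True)
class TreatmentSummary:
    """Mean kill for one treatment with a Student-t 95% CI."""

    treatment: str
    n: int
    mean_kill: float
    sd_kill: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class WelchResult:
    """Welch unequal-variance t-test with Welch-Satterthwaite df."""

    t_stat: float
    df: float
    p_value: float


@dataclass(frozen=True)
class SurvivorModelFit:
    """ANCOVA fit of log(post index) on log(pre index) x treatment.

    ``params``/``bse`` are keyed ``intercept``, ``log_pre``, ``treatment``
    (strip indicator, broadcast as reference) and ``interaction``;
    ``fvalues``/``pvalues`` hold the sequential (Type-I) per-term F tests.
    ``raw`` is the underlying statsmodels OLS results object.
    """

    params: Mapping[str, float]
    bse: Mapping[str, float]
    fvalues: Mapping[str, float]
    pvalues: Mapping[str, float]
    nobs: int
    df_resid: float
    raw: object = dataclasses.field(repr=False, default=None)


_REQUIRED_COLUMNS = ("block_id", "treatment", "transect_id", "night", "period", "count")


def counts_to_frame(records: Iterable[TransectCount]) -> pd.DataFrame:
    """Stack :class:`TransectCount` records into the canonical count table."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check the count-table schema and invariants; returns the frame."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if counts["count"].isna().any() or (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative and non-missing")
    bad_t = set(counts["treatment"]) - set(TREATMENTS)
    if bad_t:
        raise ValueError(f"unknown treatment values: {sorted(bad_t)}")
    bad_p = set(counts["period"]) - set(PERIODS)
    if bad_p:
        raise ValueError(f"unknown period values: {sorted(bad_p)}")
    key = ["block_id", "transect_id", "night", "period"]
    if counts.duplicated(subset=key).any():
        raise ValueError("duplicate (block, transect, night, period) rows")
    per_block = counts.groupby("block_id")["treatment"].nunique()
    if (per_block > 1).any():
        raise ValueError("a block must have a single treatment")
    return counts


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        return counts
    return counts_to_frame(counts)


def replicate_index(counts) -> float:
    """Abundance index for one block and period: rabbits per transect.

    Counts are averaged over nights within each transect first, then across
    transects, which equals the plain mean of all eight values for a balanced
    block but remains sensible when a night is missing.
    """
    df = _as_frame(counts)
    if len(df) == 0:
        raise ValueError("no counts")
    if df["period"].nunique() > 1:
        raise ValueError("mixed periods: pass counts from a single period")
    if df["block_id"].nunique() > 1:
        raise ValueError("mixed blocks: pass counts from a single block")
    per_transect = df.groupby("transect_id")["count"].mean()
    return float(per_transect.mean())


def percent_kill(pre_index: float, post_index: float) -> float:
    """Percentage reduction of the spotlight index, 100*(pre-post)/pre.

    Negative when the post-control index exceeds the pre-control one.
    """
    if pre_index <= 0:
        raise ValueError("undefined kill: pre-control index must be positive")
    if post_index < 0:
        raise ValueError("post-control index must be non-negative")
    return 100.0 * (pre_index - post_index) / pre_index


def _extract_kills(results, treatment: str | None) -> np.ndarray:
    vals = []
    for r in results:
        if isinstance(r, ReplicateResult):
            if treatment is None or r.treatment == treatment:
                vals.append(r.percent_kill)
        else:
            vals.append(float(r))
    return np.asarray(vals, dtype=float)


def treatment_summary(results, treatment: str | None = None) -> TreatmentSummary:
    """Mean, sample SD and 95% Student-t CI of per-replicate kills.

    ``results`` may be :class:`ReplicateResult` records (filtered by
    ``treatment``) or raw kill percentages.
    """
    kills = _extract_kills(results, treatment)
    n = kills.size
    if n < 2:
        raise ValueError("cannot form CI: need at least 2 replicates")
    mean = float(kills.mean())
    sd = float(kills.std(ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return TreatmentSummary(
        treatment=treatment or "all",
        n=int(n),
        mean_kill=mean,
        sd_kill=sd,
        ci95=(mean - half, mean + half),
    )


def combined_mean(summaries: Sequence[TreatmentSummary]) -> float:
    """Replicate-weighted mean kill across treatments, sum(n*mean)/sum(n)."""
    if len(summaries) == 0:
        raise ValueError("no summaries")
    n = np.array([s.n for s in summaries], dtype=float)
    m = np.array([s.mean_kill for s in summaries], dtype=float)
    return float((n * m).sum() / n.sum())


def welch_t(group_a, group_b) -> WelchResult:
    """Welch two-sample t-test (unequal variances), two-sided.

    Degenerate input with zero variance in both groups and equal means is
    defined as t = 0, p = 1 by convention.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return WelchResult(0.0, float(na + nb - 2), 1.0)
        return WelchResult(float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def logit_adjusted(proportions) -> np.ndarray:
    """Logit transform log(y/(1-y)) with a boundary fix for y = 1.

    For proportions exactly 1 (which would map to infinity) the complement
    (1-y) is replaced by the smallest nonzero complement observed in the
    input before transforming.
    """
    y = np.asarray(list(proportions), dtype=float)
    if np.any(y <= 0) or np.any(y > 1):
        raise ValueError("proportions must lie in (0, 1]")
    comp = 1.0 - y
    nonzero = comp[comp > 0]
    if np.any(comp == 0):
        if nonzero.size == 0:
            raise ValueError("adjustment undefined: all proportions equal 1")
        comp = np.where(comp == 0, nonzero.min(), comp)
    return np.log(y / comp)


def survivor_model(replicates, zero_adjust: float = DEFAULT_ZERO_ADJUST) -> SurvivorModelFit:
    """ANCOVA: log(post index) ~ log(pre index) * treatment.

    Zero post-control indices get ``zero_adjust`` added before the log so the
    transform stays defined without perturbing rank order.  F tests per term
    are sequential (Type I), matching the classical ANCOVA decomposition.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if isinstance(replicates, pd.DataFrame):
        df = replicates.copy()
    else:
        df = pd.DataFrame([dataclasses.asdict(r) for r in replicates])
    if len(df) < 5:
        raise ValueError("need at least 5 replicates for the survivor ANCOVA")
    if df["treatment"].nunique() < 2:
        raise ValueError("both treatments must be present")
    if (df["pre_index"] <= 0).any():
        raise ValueError("pre-control indices must be positive")
    post = df["post_index"].to_numpy(dtype=float)
    post = np.where(post == 0, post + zero_adjust, post)
    d = pd.DataFrame(
        {
            "log_post": np.log(post),
            "log_pre": np.log(df["pre_index"].to_numpy(dtype=float)),
            "is_strip": (df["treatment"] == "strip").astype(float),
        }
    )
    fit = smf.ols("log_post ~ log_pre * is_strip", data=d).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("collinear design")
    anova = anova_lm(fit, typ=1)
    names = {
        "Intercept": "intercept",
        "log_pre": "log_pre",
        "is_strip": "treatment",
        "log_pre:is_strip": "interaction",
    }
    params = {names[k]: float(v) for k, v in fit.params.items()}
    bse = {names[k]: float(v) for k, v in fit.bse.items()}
    fvalues = {names[k]: float(anova.loc[k, "F"]) for k in anova.index if k in names}
    pvalues = {names[k]: float(anova.loc[k, "PR(>F)"]) for k in anova.index if k in names}
    return SurvivorModelFit(
        params=params,
        bse=bse,
        fvalues=fvalues,
        pvalues=pvalues,
        nobs=int(fit.nobs),
        df_resid=float(fit.df_resid),
        raw=fit,
    )


class TrialEfficacy:
    """Before/after spotlight-count trial of strip vs broadcast baiting.

    Parameters
    ----------
    counts : pandas.DataFrame
        Long table with columns ``block_id, treatment, transect_id, night,
        period, count``; one row per transect per night per period.

    Examples
    --------
    >>> model = TrialEfficacy.from_csv("counts.csv")   # doctest: +SKIP
    >>> res = model.fit()                              # doctest: +SKIP
    >>> print(res.summary())                           # doctest: +SKIP
    """

    def __init__(self, counts: pd.DataFrame):
        self.counts = validate_counts(counts.copy())

    @classmethod
    def from_csv(cls, path) -> "TrialEfficacy":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, records: Iterable[TransectCount]) -> "TrialEfficacy":
        return cls(counts_to_frame(records))

    def replicate_table(self) -> pd.DataFrame:
        """Per-block pre/post indices and percentage kill."""
        rows = []
        for block_id, grp in self.counts.groupby("block_id", sort=True):
            treatment = grp["treatment"].iloc[0]
            pre = replicate_index(grp[grp["period"] == "pre"])
            post = replicate_index(grp[grp["period"] == "post"])
            rows.append(
                {
                    "block_id": block_id,
                    "treatment": treatment,
                    "pre_index": pre,
                    "post_index": post,
                    "percent_kill": percent_kill(pre, post),
                }
            )
        return pd.DataFrame(rows)

    def fit(self, zero_adjust: float = DEFAULT_ZERO_ADJUST, ancova: bool = True) -> "TrialEfficacyResults":
        """Run the full trial analysis and return a results object."""
        replicates = self.replicate_table()
        summaries: dict[str, TreatmentSummary] = {}
        for t in TREATMENTS:
            kills = replicates.loc[replicates["treatment"] == t, "percent_kill"]
            if len(kills) >= 2:
                summaries[t] = treatment_summary(kills.to_numpy(), t)
        overall = combined_mean(list(summaries.values())) if summaries else float("nan")
        welch = None
        if set(summaries) == set(TREATMENTS):
            welch = welch_t(
                replicates.loc[replicates["treatment"] == "strip", "percent_kill"],
                replicates.loc[replicates["treatment"] == "broadcast", "percent_kill"],
            )
        survivor = None
        if (
            ancova
            and len(replicates) >= 5
            and replicates["treatment"].nunique() == 2
        ):
            survivor = survivor_model(replicates, zero_adjust=zero_adjust)
        return TrialEfficacyResults(
            replicates=replicates,
            summaries=summaries,
            overall_mean_kill=overall,
            welch=welch,
            survivor=survivor,
            zero_adjust=zero_adjust,
        )


@dataclass
class TrialEfficacyResults:
    """Fitted trial-efficacy statistics; returned by :meth:`TrialEfficacy.fit`."""

    replicates: pd.DataFrame
    summaries: Mapping[str, TreatmentSummary]
    overall_mean_kill: float
    welch: WelchResult | None
    survivor: SurvivorModelFit | None
    zero_adjust: float

    def kill_moments(self) -> dict[str, tuple[float, float]]:
        """Per-treatment (mean, variance) of the kill as fractions in (0,1).

        These are the plug-in moments used to parameterize the beta efficacy
        law of the recovery simulator.
        """
        out = {}
        for t, s in self.summaries.items():
            out[t] = (s.mean_kill / 100.0, (s.sd_kill / 100.0) ** 2)
        return out

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index=False)

    def summary(self) -> str:
        """Human-readable text report of the fitted statistics."""
        buf = io.StringIO()
        w = buf.write
        w("Aerial 1080 trial efficacy (spotlight-count index)\n")
        w("=" * 58 + "\n")
        w(f"{'treatment':<11}{'n':>3}{'mean kill %':>13}{'sd':>8}{'95% CI':>18}\n")
        for t, s in self.summaries.items():
            ci = f"({s.ci95[0]:.1f}, {s.ci95[1]:.1f})"
            w(f"{t:<11}{s.n:>3}{s.mean_kill:>13.1f}{s.sd_kill:>8.2f}{ci:>18}\n")
        w("-" * 58 + "\n")
        w(f"Overall mean kill (replicate-weighted): {self.overall_mean_kill:.1f}%\n")
        if self.welch is not None:
            w(
                f"Welch t-test strip vs broadcast: t_{self.welch.df:.2f} = "
                f"{self.welch.t_stat:.2f}, P = {self.welch.p_value:.2f}\n"
            )
        if self.survivor is not None:
            w("ANCOVA log(post) ~ log(pre) * treatment (Type-I F):\n")
            for term in ("log_pre", "treatment", "interaction"):
                w(
                    f"  {term:<12} beta = {self.survivor.params[term]:+.3f} "
                    f"(SE {self.survivor.bse[term]:.3f}), "
                    f"F = {self.survivor.fvalues[term]:.2f}, "
                    f"P = {self.survivor.pvalues[term]:.3f}\n"
                )
        return buf.getvalue()

    def plot(self, ax=None):
        """Log-log scatter of post- vs pre-control indices by treatment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for t, marker in zip(TREATMENTS, ("o", "D")):
            sub = self.replicates[self.replicates["treatment"] == t]
            post = sub["post_index"].where(sub["post_index"] > 0, self.zero_adjust)
            ax.scatter(sub["pre_index"], post, marker=marker, label=t)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("pre-control rabbits per transect")
        ax.set_ylabel("post-control rabbits per transect")
        ax.legend()
        return ax
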