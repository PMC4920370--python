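# Methods

## Trial efficacy statistics

A replicate (treatment block) is summarized by one pre- and one post-control
abundance index: counts are averaged over the two nights within each
transect first, then across the four transects. For balanced blocks this
equals the mean of all eight counts; for blocks missing a night it weights
transects equally rather than nights, which is the robust choice when a
night's survey is lost to weather. The percentage kill
100·(pre − post)/pre is computed per replicate and then averaged — replicate
blocks, not pooled counts, are the experimental unit.

Treatment-level CIs use the Student t quantile, not the normal: at n = 9 and
10 replicates the difference is material (t₀.₉₇₅,₈ = 2.31 vs 1.96) and t is
what the replicate-level analysis implies. The two treatments are compared
with Welch's unequal-variance t-test (Welch–Satterthwaite df, two-sided p);
the degenerate zero-variance/equal-means case is defined as t = 0, p = 1.
No multiple-testing correction is applied anywhere. The survivor ANCOVA fits
log(post) ~ log(pre) × treatment by OLS (statsmodels) and reports sequential
(Type-I) F tests, the classical ANCOVA decomposition; with 19 replicates and
4 parameters the per-term denominators have 15 df. Replicates with a
post-control index of exactly 0 would break the log transform; they get
+0.0625 (half of 1/8, the smallest possible nonzero index from 4 transects ×
2 nights) added first. The adjustment is configurable (`zero_adjust`) and
affects only its own replicate's leverage, not rank order. The logit
transform for proportion-scale modelling maps y = 1 to log(1/min nonzero
(1−y)) over the input, the standard boundary fix for sample proportions at 1.

## Sowing geometry

A plan is a uniform-density band model: swath width w deposited every
FPS metres at a block-averaged sowing rate R kg/ha. Derived identities:
coverage fraction w/FPS, gap FPS − w, within-strip mass density
(R·1000/10⁴)/(w/FPS) g/m², count density = mass density / mean bait mass,
toxin loading R·1000·(toxin mass fraction) g/ha. The "effective swath" of a
real aircraft pass (vortex-spread, 5%-trimmed) is an *input*, not modelled —
there is no spatial scatter model in scope. Mass bins use <4 g strict,
[4, 6] g closed, >6 g strict, so boundary masses land in the middle bin.
Observed field count densities (e.g. ~1.1 baits/m² in ~23 m strips at
10 kg/ha) are only consistent with a mean collected-piece mass well below
the 6 g nominal dice, i.e. with substantial bait fragmentation; the
geometry module therefore treats mean bait mass as a free parameter and the
synthetic fragmentation model (below) supplies realistic values.

## Recovery model

The growth law is a deliberate stand-in: deterministic logistic growth
dN/dt = r N (1 − N/K) with K normalized to the pre-control density. Field
studies of this kind parameterize richer semi-arid rabbit population models
whose internals (seasonal structure, density-dependence shape) are not
reproducible from their summary outputs, so all growth parameters here are
configuration, none hard-coded. Defaults: r_pre-RHD = 1.0/yr (with q = 0.95 this calibrates the
strip-sown pre-RHD scenario to a ~5.5–5.6 y recovery, matching the published
scale); the post-RHD regime is exactly r/2. An optional breeding-season
window sets r to zero outside inclusive day-of-year bounds and rescales it
inside so the annual integral still equals r.

Numerics: the simulator advances in dt = 1 day steps using the *exact*
logistic flow map N ← K·N/(N + (K−N)e^(−r_eff·dt)), which solves the ODE
exactly for piecewise-constant r (including the seasonal window), and the
threshold crossing is interpolated within the step from the same closed
form. Recovery times are therefore not quantized to the step and the
degenerate-kill simulator agrees with the analytic recovery time
t = (1/r)·ln[q(1−s)/(s(1−q))] to machine precision. A first-order Euler
update (`method="euler"`) is retained for discretization-error studies; at
dt = 1 day it carries an O(r²·dt·t/2) time bias of ~3 days over a 5.5-year
recovery, which is why it is not the default.

"Reached pre-control density" is asymptotically unreachable under logistic
growth, so recovery is defined as reaching a threshold fraction q of K,
default 0.95 and exposed in every config; the CLI `simulate --q-sensitivity`
flag reports mean recovery at q = 0.90/0.95/0.99. Runs not recovered by the
horizon (default 100 y) are counted and excluded from summary statistics
with a warning. Efficacy draws use a beta law parameterized by moments from
a treatment's kill mean and variance; a `FixedKill` point mass exists for
oracle tests. One seeded generator drives each run batch, and the scenario
order is fixed (pre/strip, pre/broadcast, post/strip, post/broadcast), so
results are bit-reproducible for a fixed seed.

Under pure logistic growth, halving r exactly doubles every recovery time,
so the post-/pre-RHD mean-recovery ratio is exactly 2.0 — at the top of the
1.5–2.0 band that richer density-dependent models (with seasonal structure
and non-logistic density dependence) produce. Where the ratio itself is
reported, the r-halved pair is simulated with common random numbers (same
beta draws), a variance-reduction choice that makes the ratio exact rather
than straddling its deterministic value by Monte-Carlo noise.

## Cost model

Fractional operation counts are retained (a 20-year horizon divided by a
5.5-year frequency is 3.64 operations): cost accrues pro-rata, so
cost/ha/yr = cost-per-op/frequency identically and the horizon cancels.
Defaults: broadcast $NZ 100/ha/operation, strip 25% less ($NZ 75), 20-year
horizon, 2,000 ha farm. Savings are computed from unrounded intermediates;
hand arithmetic on values rounded to 1–2 dp can differ by ~$10–20/yr, which
the CLI output footnotes. Discounting/NPV and secondary follow-up control
are out of scope.

## Synthetic trial generator

The generator emulates the study conditions the analysis assumes: 9
strip-sown + 10 broadcast blocks, 4 transects × 2 nights per period, latent
pre-control densities log-uniform on 10–155 rabbits/transect, true kills
drawn from treatment-specific beta laws (strip: moments (0.927, 0.0358²);
broadcast: (0.940, 0.0622²) — SDs back-derived from t-based 95% CIs at n = 9
and 10), post-control latent means thinned by the true kill, and observed
counts negative-binomial around the latent transect means. NB rather than
Poisson noise is a stated assumption, not an observed distribution: the
dispersion default k = 30 reproduces a mean absolute night-to-night
difference of ~18 rabbits at a pre-control mean of ~76 (Poisson would give
~10). `night_dispersion=None` is the noise-free limit returning exact
(fractional) expected counts, in which the kill estimator is exact. A
contamination option (off by default) injects one anomalously low 77% kill
into a broadcast block, mimicking the kind of single-operation failure seen
in field series. Bait masses come from a fragmentation mixture — nominal
~N(6, 1) g dices of which a fraction p = 0.45 break into two Beta(2,2)-split
pieces — tuned so collected-piece masses land near the observed
(<4 g, 4–6 g, >6 g) fractions of (0.46, 0.36, 0.18).

What the generator does *not* emulate: spatial transect placement and edge
effects, detection-distance variation, immigration between blocks, within-
block density gradients, and any direct RHD epidemic dynamics. Passing
calibration tests therefore show the estimators are correct *under the
assumed count model*, not that real spotlight counts satisfy it.

## Problem sizes

Monte-Carlo batches default to 10,000 runs per scenario. Calibration checks
use 200 synthetic trial series (parameter-recovery coverage), 400 series for
the Welch type-I rate, and 10⁶ draws for the beta moment round-trip — sizes
at which binomial/Monte-Carlo standard errors are small relative to the
properties being asserted while the whole suite stays fast.

## Known limitations

- The logistic stand-in ignores seasonal age structure and any Allee or
  predation effects; its recovery times are calibration-scale, not
  field predictions, and the post-RHD times in particular run ~15% longer
  than a seasonal density-dependent model would give (the exact-doubling
  property above).
- Kill variance is estimated from ≤10 replicates per treatment, so the beta
  laws' tails are poorly identified; the broadcast fit (β < 1) puts
  appreciable mass very close to 100% kill.
- The trial CSV schema assumes raw per-night integer counts; pre-averaged
  inputs will validate but double-shrink the night noise.
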