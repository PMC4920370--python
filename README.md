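# baitsow

Strip- versus broadcast-sowing of aerial 1080 bait for European rabbit
(*Oryctolagus cuniculus*) control: trial kill statistics, sowing geometry,
population-recovery simulation and farm-plan cost modelling.

## The problem

Aerial broadcast sowing of sodium-fluoroacetate ("1080") carrot bait is the
frontline method for suppressing high-density rabbit populations on New
Zealand's semi-arid rangelands, but it is expensive and applies a lot of
toxin per hectare. Strip-sowing deposits the same high *local* bait density
in narrow swaths separated by unbaited gaps (e.g. 10 m swaths every 75 m of
flight-path spacing instead of full 25 m coverage), cutting bait — and toxin
— use by about two thirds. Because the gaps are smaller than a rabbit's home
range, kill rates should be comparable. `baitsow` is for wildlife-management
analysts who need to (a) estimate operation efficacy from before/after
spotlight transect counts, (b) reason about sowing-plan geometry, and
(c) project how often control must be repeated and what a 20-year farm plan
costs under each method.

## What it computes

**Trial efficacy.** Each replicate block is monitored with four 800 m
spotlight transects on two consecutive nights pre- and post-control. The
replicate index is the mean count per transect, and the percentage kill is

    kill% = 100 (pre − post) / pre .

Treatment means carry Student-t 95% CIs (mean ± t₀.₉₇₅,ₙ₋₁ · SD/√n), the two
sowing methods are compared with a Welch unequal-variance t-test, and an
ANCOVA of log survivors, log(post) ~ log(pre) × treatment, asks whether more
rabbits survive where more were present initially. A boundary-adjusted logit
transform (for kill proportions equal to 1) is provided for proportion-scale
modelling.

**Recovery simulation.** Population density is normalized to carrying
capacity K = pre-control density. An operation on 1 July kills a
beta-distributed fraction c of the population, with the beta law fitted by
moments to a treatment's observed kill mean m and variance v:

    α = m (m(1−m)/v − 1),   β = (1−m) (m(1−m)/v − 1) .

Survivors N₀ = K(1−c) grow back along dN/dt = r·N(1−N/K) (optionally with a
seasonal breeding window), and each Monte-Carlo run records the years until
density reaches q·K (default q = 0.95). The post-RHD (Rabbit Haemorrhagic
Disease) regime uses exactly r/2.

**Costs.** The mean years-to-recovery is the interval between operations;
costs accrue pro-rata, so cost/ha/yr = cost-per-operation / frequency. The
farm-scale saving of strip over broadcast sowing is the per-ha cost
difference times farm area, per year or per management horizon.

## Worked example

Run the full four-scenario workflow on a synthetic 19-block trial series
(9 strip-sown, 10 broadcast replicates, Central Otago-like conditions):

```
$ baitsow all --outdir demo --seed 7
Aerial 1080 trial efficacy (spotlight-count index)
==========================================================
treatment    n  mean kill %      sd            95% CI
strip        9         93.6    4.26      (90.3, 96.9)
broadcast   10         95.2    4.68      (91.8, 98.5)
----------------------------------------------------------
Overall mean kill (replicate-weighted): 94.4%
Welch t-test strip vs broadcast: t_16.99 = -0.76, P = 0.46
...
          scenario  frequency_years  cost_per_ha_year
     pre_rhd_strip             5.87             12.78
 pre_rhd_broadcast             6.49             15.41
    post_rhd_strip            11.74              6.39
post_rhd_broadcast            13.00              7.69
```

Reading this: both methods kill ~94% of rabbits and the Welch test finds no
difference (P = 0.46). Fitting beta efficacy laws to the two treatments and
simulating recovery (r = 1.0/yr pre-RHD) says strip-sown land needs retreating
every ~5.9 years versus ~6.5 for broadcast — broadcast's slightly higher kill
buys slightly slower rebound — but at $NZ 75 vs $NZ 100 per hectare per
operation, strip-sowing is still ~$2.60/ha/yr cheaper.

Individual stages: `baitsow synth` (generate trial data + latent truths),
`baitsow efficacy counts.csv`, `baitsow plan --pattern strip
--sowing-rate-kg-ha 10 --fps-m 75 --swath-m 10` (prints the 65 m gap,
1.25 baits/m² within-strip density and 2 g/ha toxin loading),
`baitsow simulate --config scenario.yaml --q-sensitivity`, and
`baitsow costs --recovery recovery.json`.

As a library:

```python
from baitsow import TrialEfficacy
res = TrialEfficacy.from_csv("counts.csv").fit()
print(res.summary())
res.kill_moments()   # per-treatment (mean, var) kill fractions for the beta fit
```

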