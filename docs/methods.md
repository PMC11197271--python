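# Methods

## The outcome statistic

A scan enters the analysis as a node × frame matrix of parcel-averaged BOLD
series (360 cortical parcels at full scale; TR = 0.7 s; 645 retained frames
after dropping five non-steady-state volumes from a 650-frame run). The
connectome is the matrix of pairwise Pearson correlations over frames,
Fisher-transformed (z = atanh r) to stabilize variance. Network-restricted
strength (NRS) is the unweighted mean of z over the n(n−1)/2 unordered pairs
inside one network of a six-network atlas (DMN, CE, DS, VS, SM, VI);
self-pairs are excluded, and |r| is clipped at 1 − 1e-7 before atanh so
degenerate series produce a large finite z rather than infinity. Because
every node appears in the same number of pairs, the pair-mean equals the
mean of per-node nodal strengths; the code computes the former and asserts
the identity against the latter.

Cleanup before the connectome, when starting from raw parcel series, follows
the order: drop initial frames → motion-confound regression → mean-timeseries
regression. Motion expansion is the standard 24-parameter set: the six
rigid-body series, their backward first differences (first element set to 0,
keeping the frame count constant), and the squares of both. Confound
regression always includes an intercept; exactly-collinear columns are
dropped with a warning rather than an error. Mean-timeseries regression
residualizes each node on the across-node mean series plus intercept — the
parcel-level analogue of global-signal regression — and errors on a
zero-variance mean series.

## The 2 × 2 repeated-measures model

The primary inference is a mixed-design GLM: diagnostic group (PTSD vs MDD)
between subjects, scan (pre vs post stressor) within subjects, NRS as
outcome. With two levels per factor the three F tests reduce exactly to
t-tests, and that reduction *is* the implementation:

* group: independent pooled-variance t on per-subject two-scan means, F = t²;
* interaction: the same t on post-minus-pre difference scores, F = t²;
* stress: one-sample t on the unweighted average of the two group mean
  differences, using the pooled difference variance (so unequal group sizes
  do not reweight the main effect).

All three are reported on df (1, N − 2). The reduction doubles as an oracle:
tests assert F = t² against independent scipy t-tests to 1e-10 on random
cohorts. The covariate-adjusted interaction regresses difference scores on
the group indicator plus mean-centered between-subject covariates; constant
covariates are dropped (leaving F unchanged), collinear pairs are an error,
and df2 = N − 2 − k for k retained covariates (52 subjects and 11 covariates
give df2 = 39).

Conventions, logged at run time: "reduction" contrasts are reported as
positive magnitudes with a direction field while arithmetic keeps signed
post − pre (within) and PTSD − MDD (between) values; percent differences use
the group's pre-stress mean for stress effects and the MDD mean of the same
condition for group effects; the 2×2 identity (Δ_PTSD − Δ_MDD) =
(group-difference post − group-difference pre) is asserted exactly. The
demographic chi-square is Pearson's without continuity correction (the
convention that reproduces standard statistical-package output for these
tables); Mann-Whitney uses exact enumeration when both samples have n ≤ 8
without ties and the tie-corrected normal approximation (no continuity
correction) otherwise; multiple-comparison adjustment is Benjamini-Hochberg
step-up with Bonferroni behind a flag. A correlation of |r| = 1 returns
p = 0 with a degeneracy flag instead of erroring, since tiny simulated
cohorts can produce it.

The split-half duration analysis re-runs the same 2×2 model with the within
factor replaced by scan half. Halves are contiguous and equal-length; an odd
frame count drops the single middle frame so the two halves cover identical
durations (an unequal split would itself be a duration confound). The nodal
exploration contrasts per-node nodal strength between groups post-stressor
(pre-stress available behind a flag), reporting raw and FDR-adjusted
p-values sorted by |effect|.

## Power analysis

Each GLM effect maps to the t-test its 2×2 reduction produces: stress → a
one-sample t on all N difference scores (δ = d√N, df = N − 1); interaction →
a two-sample t on difference scores (δ = d√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2);
group → a two-sample t on two-scan averages. The group design assumes the
two scans are uncorrelated, so averaging halves the variance and a Cohen's d
on the single-scan scale inflates by √2; the assumption is explicit and
configurable through `scan_correlation` (ρ = 0 default; the general factor
is √(2/(1+ρ))). Power is the two-tailed noncentral-t tail mass beyond the
central-t critical value; `mdes` inverts it by bracketing to 1e-8 on
d ∈ [1e-6, 10]. A normal-approximation mode ships alongside the exact one
because published power tables are frequently computed that way and the two
differ by about 0.01 in d at some cells; empirical validation simulates each
design's t-test directly (10,000 replicates) and checks the rejection rate
against the analytic value.

## Synthetic cohorts

The generator emulates the study design — 28 PTSD and 24 MDD subjects, two
scans each, block-structured correlations organized by a six-network atlas
whose DMN holds about a fifth of the nodes (75 of 360 at full scale) — in
two modes.

**Timeseries mode** draws each scan from a zero-mean multivariate normal
whose correlation matrix has atanh⁻¹-block structure: within-network z =
atanh(ρ_within), between-network z = atanh(ρ_between). All injected effects
act additively in Fisher-z space and are back-transformed, so they are exact
on the analysis scale (which averages z, not r): a subject-level offset
(SD `subject_sd` = 0.033), a scan-level offset (SD `scan_sd` = 0.08), a
group × scan interaction decrement of d·√2·`scan_sd` on PTSD post scans
(making the population standardized difference-score effect equal d), an
optional within-run drift added to the second half of each run, and an
optional focal decrement on pairs touching designated DMN nodes. Subject and
scan offsets use a bounded (uniform) distribution scaled to the requested
SD: an equicorrelated block of m nodes stops being positive semidefinite
when its correlation falls below −1/(m−1), and the generator's policy on a
non-PSD matrix is to fail loudly with the offending eigenvalue rather than
silently project — bounded jitter makes the worst case provably safe at the
defaults, where Gaussian tails would trip the check at random. Scans are
generated white (no autocorrelation) by default so closed-form expectations
hold exactly; an AR(1) option exists for realism checks. Default scale is
reduced (60 nodes, 200 frames, 10 + 10 subjects) with the full design behind
`SimConfig.study_scale()`.

**Strength mode** skips timeseries and draws the outcome directly:
pre ~ N(0.13, 0.033²) and post = pre + shift_group + N(0, 0.026²), the means
and SDs matching the magnitudes the strength analysis operates on (a DMN
strength near 0.13, between-subject SD implied by a group-difference SEM of
~0.009, difference-score SD implied by a paired SEM of ~0.005 at n = 28).
The PTSD shift is −d·0.026, so the standardized interaction effect equals
the configured d exactly; this is the fast path for the type-I-error and
power experiments. Covariates (age truncated-normal 41.4 ± 10 on [21, 68],
sex Bernoulli(0.67), lognormal motion around 0.10, comorbidity flags at the
study's base rates, QIDS/PCL-5/CAPS-subscale scores) are decorative
realism — none is load-bearing for any calibration claim.

What the generator does **not** emulate: hemodynamic forward models,
physiological noise and scanner drift, motion spikes, heterogeneous
node-level connectivity within a network, and between-scan correlation of
the two resting runs (scans are conditionally independent given the subject
offset). Passing tests therefore validate the estimator and inference
machinery under a clean, calibrated model, not robustness to those realisms.

## Numerical choices and limitations

* Estimation noise: the NRS of a simulated scan has sampling SD ≈ 0.029 at
  60 nodes/200 frames and ≈ 0.013 at 360/645 (measured). In timeseries mode
  this noise adds to the difference-score SD and attenuates the realized
  standardized effect by a few percent at the default `scan_sd`; the
  small-sample inflation of the plain Cohen's d estimator offsets most of
  it, and the parameter-recovery test bounds the net bias at ±0.05.
* Orthogonality/validation tolerances: residual-regressor inner products
  < 1e-8 × frames; symmetry to 1e-12; nodal-mean identity to 1e-12;
  mdes round trip to 1e-6.
* Degenerate inputs: zero-variance nodes are an error naming the node; an
  all-constant cohort yields F = 0 rather than 0/0; a constant set of
  difference scores is a flagged degenerate SEM.
* Experiment sizes in the test suite and acceptance script (5000 null
  replicates, 2000 power replicates, 200 localization replicates at reduced
  scale) were chosen to bound Monte-Carlo error well inside each asserted
  band while keeping a full run in tens of seconds.
* The real study's F statistics cannot be reproduced here because its data
  are available only on request; the suite validates the identical machinery
  on synthetic ground truth instead, and the exact DMN membership of the
  published atlas is likewise replaced by a configurable stand-in partition.
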