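# netstress

Network-restricted strength analysis of pre/post-stressor resting-state fMRI
connectomes.

Resting-state functional connectivity studies of posttraumatic stress
disorder (PTSD) and major depressive disorder (MDD) often summarize a brain
network's integrity by one number: the **network-restricted strength (NRS)**
of an intrinsic connectivity network, i.e. the mean Fisher-z-transformed
Pearson correlation over all node pairs inside the network. For the default
mode network (DMN) of a 360-parcel cortical atlas this is "DMN strength":

```
r_ij = corr(x_i, x_j)          pairwise Pearson correlation over frames
z_ij = atanh(r_ij)             Fisher variance-stabilizing transform
NRS  = mean{ z_ij : i < j, i, j in the network }
```

`netstress` implements, as a tested reusable library, the full analysis
design built around that statistic for a two-group, two-scan study in which
each participant is scanned immediately before and after an in-scanner
affective stressor:

* **atlas_io** — TSV (and read-only CIFTI-2 ptseries) I/O for parcellated
  timeseries and node→network atlases; post-preprocessing cleanup (initial
  frame dropping, 6→24 motion-confound expansion, confound regression, mean
  timeseries regression).
* **connectome** — correlation matrices, Fisher z, NRS, per-node nodal
  strength, split-half scans.
* **inference** — the 2 (group) × 2 (pre/post) repeated-measures GLM via its
  exact reduction to t-tests (group F = t² on subject means; interaction
  F = t² on difference scores; stress effect from unweighted group mean
  differences), simple effects and percent differences, covariate-adjusted
  interaction, severity correlations, 2×2 chi-square, Mann-Whitney, and
  Benjamini-Hochberg FDR.
* **power** — minimum detectable Cohen's d and power for each effect through
  the noncentral t distribution.
* **synthetic** — seeded cohort generation, either full block-covariance
  multivariate-normal timeseries or NRS values directly, with injectable
  group/stress/interaction/drift/nodal effects of known size.
* **pipeline** — one-call orchestration producing a deterministic JSON/CSV/
  text report; a thin `netstress` CLI (`simulate` / `analyze` / `power`).

## Worked example

`examples/01_simulate_and_analyze.py` simulates a reduced-scale cohort
(10 PTSD + 10 MDD subjects, 60 nodes, 200 frames) with a large injected
group × stress interaction (d = 1.5) and runs the whole battery:

```
netstress analysis report (v0.1.0)
========================================
       group: F(1,18) = 7.598, p = 0.0130
      stress: F(1,18) = 10.767, p = 0.0041
 interaction: F(1,18) = 7.032, p = 0.0162
simple effect PTSD: 56% decrease (mean diff 0.1755, SEM 0.0431, p = 0.003)
simple effect MDD: 6% decrease (mean diff 0.0186, SEM 0.0405, p = 0.657)
group contrast pre: 0% (mean diff 0.0009, SEM 0.0433, p = 0.983)
group contrast post: 53% (mean diff 0.1578, SEM 0.0391, p = 0.001)
covariate-adjusted interaction: F(1,14) = 9.732, p = 0.0075
```

The interaction row is the primary test: the stressor reduced DMN strength
in the simulated PTSD group but not in MDD, so the within-group (simple
effect) contrast is significant only for PTSD and the between-group contrast
only post-stress — exactly the signature the injected effect should produce.
Percentages are the contrast magnitude relative to the comparison mean (the
group's pre-stress mean for stress effects, the MDD mean for group effects).

Other examples: `examples/02_power_table.py` prints the minimum detectable
Cohen's d per effect and power level for n = 28/24;
`examples/03_nodal_localization.py` demonstrates that the nodal exploration
recovers a deficit injected into three designated DMN nodes.

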