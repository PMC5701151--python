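# ebnt — EEG brain-network topology toolkit

`ebnt` is a tested, reusable pipeline for resting-state EEG
functional-network analysis: phase-lag-index (PLI) connectivity plus
three graph-topology characterizations — the weighted graph, the
density-thresholded binary graph and the minimum spanning tree (MST) —
with two-group statistics on every measure.  It is aimed at
electrophysiologists and methods researchers who want to compare
whole-brain network organization between groups (e.g. a clinical and a
control cohort) and to validate such comparisons against synthetic
cohorts with known ground truth.

## The method

**Connectivity.** For two signals with instantaneous phase difference
Δφ(t_k), the phase lag index is

    PLI = | ⟨ sign Δφ(t_k) ⟩ |  ∈ [0, 1],

the absolute mean sign of the wrapped phase-difference series.  It is 1
for a consistent non-zero lag and 0 for independent signals *or* for
coupling at 0 mod π — which makes it insensitive to volume-conduction
crosstalk.  Per subject and frequency band (δ 1–4, θ 4–8, α 8–13,
β 13–30, γ 30–48 Hz), signals are band-passed with zero-phase FIR
filters, split into non-overlapping 5 s segments, and the per-segment
N×N PLI matrices are averaged into one connectivity matrix.

**Graph topology.** Three views of each connectivity matrix:

* *Weighted graph* — clustering coefficient
  CC_i = Σ w_ik w_il w_kl / Σ w_ik w_il and harmonic-mean shortest-path
  length on distances d = 1/w, both normalized by the mean over 100
  surrogate networks with randomly reshuffled edge weights.
* *Binary graph* — the strongest `density · N(N−1)/2` edges are kept at
  each link density on a 0.20–0.90 grid (step 0.05), and binary
  clustering and path length are computed at every density, so groups
  are compared at equal edge counts.
* *Minimum spanning tree* — with similarity weights the minimum-cost
  tree is the *maximum* spanning tree (Kruskal); its leaf fraction,
  maximum betweenness centrality BC_max and tree hierarchy
  TH = LN / (2 m BC_max) (m = N−1 edges; 0.5 for a star, → 0 for a long
  line) compare network backbones without any thresholding step.

**Statistics.** Per measure × band (× density): Shapiro–Wilk screen,
independent two-sample t-tests, Bonferroni correction within each graph
method's measure family (the binary sweep also corrects for its 15
densities), significance at corrected p < 0.01 with a marginal tier up
to 0.05.  Edgewise connectivity maps use per-edge t-tests with
Benjamini–Hochberg FDR control.

**Synthetic cohorts.** `ebnt.cohort` generates two-group multichannel
cohorts in which chosen channel pairs share band-limited carriers with
consistent non-zero lags (the condition PLI detects), a hub-biased
coupling layout (heavy-tailed hubness profile), and a configurable
multiplicative coupling reduction in selected bands for group 2 — so
every downstream stage can be validated against known ground truth.
See `docs/methods.md` for the full model and its limitations.

## Worked example

Generate a small cohort in which group 2 has its alpha-band coupling
halved, run the pipeline, and compare groups:

```python
import numpy as np
from ebnt import (AnalysisConfig, BandCoupling, CohortConfig, analyze_cohort,
                  band_by_name, compare_groups, generate_cohort,
                  report_markdown)

config = CohortConfig(
    n_subjects_per_group=6,
    duration=60.0,
    n_channels=32,
    band_coupling={"alpha": BandCoupling(strength=0.9, phase_lag=np.pi / 4,
                                         fraction_of_pairs=0.2)},
    group_effect={"alpha": 0.5},   # group 2: alpha coupling halved
    seed=7,
)
recordings = generate_cohort(config)

analysis = AnalysisConfig(bands=(band_by_name("alpha"),),
                          analyses=("connectivity", "weighted", "mst"))
metrics, matrices = analyze_cohort(recordings, analysis)
print(report_markdown(compare_groups(metrics)))
```

which prints:

```
# Group comparison report

## alpha band

| measure | density | t | p (corrected) | tier |
|---|---|---|---|---|
| cc_norm |  | 9.080 | 7.645e-06 | significant |
| leaf_fraction |  | 5.578 | 0.0004693 | significant |
| mean_pli |  | 9.183 | 3.452e-06 | significant |
| pl_norm |  | -4.629 | 0.001876 | significant |
| tree_hierarchy |  | 2.749 | 0.04106 | marginal |

4 of 5 comparisons significant at corrected p < 0.01.
```

Positive t means group 1 (intact coupling) scores higher: the reduced
cohort shows lower mean PLI (weaker overall connectivity), lower
normalized clustering and leaf fraction (a less clustered, less
hub-dominated — more line-like — network backbone), exactly the
injected effect.  The same analysis is available from the shell:

```sh
ebnt synth --config cohort.yaml --out cohort/
ebnt run --config analysis.yaml --cohort cohort/ --out results/
```

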