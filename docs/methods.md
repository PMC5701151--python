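# Methods

This note records the models, conventions and design choices behind
`ebnt`, in enough detail to reproduce or audit any number the package
computes.

## Signal conditioning

The processing order is: re-reference → downsample → notch → band-pass
→ segment.

* **Re-referencing** subtracts the mean of named reference channels
  (typically the two mastoids) from every channel.
* **Downsampling** applies an anti-alias FIR before decimation
  (`scipy.signal.decimate`, staged for large factors).  The target rate
  must divide the original rate.
* **Notch** is a zero-phase FIR band-stop spanning ±2 Hz around the
  line frequency (48–52 Hz for 50 Hz mains).
* **Band-pass** filters are zero-phase (forward–backward) Hamming-window
  FIRs with transition bandwidth 25 % of the lower band edge.  Zero
  phase is not a nicety here: the phase lag index is a statistic of
  instantaneous phase differences, and any phase distortion in the
  filter would bias it.  Forward–backward application of a linear-phase
  FIR has exactly zero phase response.
* **Segmentation** cuts non-overlapping 5 s windows; a trailing partial
  window is discarded.

Band definitions are the five clinical rhythms: delta 1–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–48 Hz.  Synthetic cohorts are
generated clean at 250 Hz, so re-reference/downsample/notch are
identity-safe no-ops for them and matter only for real recordings.
Artifact removal (ocular/muscular) is out of scope: real data are
expected to arrive already cleaned.

## Phase lag index

Phases come from the analytic signal (Hilbert transform) of each
band-passed segment.  For a channel pair, the phase-difference series
is wrapped into (−π, π] and

    PLI = | mean( sign Δφ ) |.

Conventions that matter:

* **Three-valued sign.**  Samples with Δφ exactly 0 contribute 0, so
  identical signals score exactly 0.  The wrap is implemented as
  `π − mod(π − Δφ, 2π)`, which is exact at Δφ = 0 (a naive
  `angle(z₁ · z̄₂)` of analytic signals leaves ~1e−18 imaginary residue
  and never hits sign(0)).
* **No edge trimming.**  Segments are analyzed whole; Hilbert edge
  effects are part of the tolerance of phase tests, not removed.
* Per-segment PLI matrices are averaged arithmetically over segments.
  Averaging magnitudes keeps the small positive finite-sample floor of
  each segment: for independent *narrowband* signals the floor scales
  like one over the square root of the number of effective samples
  (cycles × relative bandwidth), about 0.10–0.15 in the alpha band at
  5 s segments.  Group comparisons are unaffected (both groups share
  the floor), but absolute PLI values should not be read as zero-based.

## Weighted graph measures

* Node clustering is the triple-product ratio
  CC_i = Σ_{k≠i} Σ_{l≠i,k} w_ik w_il w_kl / Σ_{k≠i} Σ_{l≠i,k} w_ik w_il
  (vectorized as (W³)_ii over strength² − Σw²; the k = l terms vanish
  because the diagonal is zero), network CC is the node mean, and a
  node with zero denominator (isolated) counts as CC_i = 0.
* Path length uses distances d = 1/w (w = 0 means no edge), Dijkstra
  shortest paths, and the *harmonic* mean over ordered pairs
  PL = 1 / mean(1/l_ij): disconnected pairs contribute a zero
  reciprocal instead of an infinite summand, so sparse graphs remain
  comparable.  A fully disconnected graph reports PL = ∞.
* Both raw measures scale with overall connection strength (w → c·w
  gives CC → c·CC, PL → PL/c), so they are normalized by the mean over
  an ensemble of 100 surrogate networks obtained by uniformly permuting
  the upper-triangle weights (symmetry and zero diagonal preserved).
  The surrogate ensemble shares the weight multiset and size — nothing
  else — with the original network, so cc_norm and pl_norm are
  scale-invariant and measure topology against weight-matched random
  networks.  The surrogate RNG seed is recorded in the output.

## Binary graph measures

Binarizing at an absolute threshold confounds topology with overall
connectivity strength (the weaker group gets fewer edges), so group
analyses binarize at fixed *link density*: the strongest
`round(density · N(N−1)/2)` edges are kept, over a density grid of
0.20–0.90 in steps of 0.05 (15 values).  Ties at the cutoff weight are
broken deterministically by ascending node-index pair.  Binary
clustering is the mean fraction of closed neighbor pairs (nodes with
degree < 2 count 0); binary path length is the harmonic mean of
minimum-edge-count distances with the same disconnected-pair convention
as above (recorded choice: low-density graphs may disconnect and are
not restricted to their giant component).  Absolute-threshold
binarization is provided as a utility only.

At high densities (≥ ~0.8) the binary path length is a function of the
edge count alone (every non-adjacent pair sits at distance 2), and the
edge count is fixed by the density — so the measure is constant across
subjects and the group test is degenerate.  Such cells are flagged
`degenerate` in the comparison table rather than tested.

## Minimum spanning tree

With similarity weights, minimum link cost (cost = inverse strength)
means *maximum* total weight, built with Kruskal's algorithm: edges in
descending weight, union–find cycle rejection, N−1 edges.  Equal
weights are ordered by ascending node-index pair; if an excluded edge
ties an accepted one the tree is non-unique and the result carries a
`ties_broken` flag.  Zero weights are treated as absent edges and a
disconnected input raises an error naming the components.

Tree measures: leaf number LN (degree-1 nodes), leaf fraction LN/N
(the literal fraction of leaf nodes; LN/(N−1) is available as an
option), maximum normalized betweenness centrality BC_max (fraction of
the (N−1)(N−2)/2 pairs whose unique tree path crosses the node), and
tree hierarchy

    TH = LN / (2 · m · BC_max),    m = N − 1.

The edge-count normalization in the denominator is a deliberate
choice: the widely quoted form LN / (2 BC_max) with BC in [0, 1] gives
a star TH = (N−1)/2, contradicting the stated range (0, 1] and the
star limit of 0.5 that the measure is defined to have.  Normalizing by
m reproduces every stated limit exactly — star = 0.5 for any N, line
→ 0 as N grows, intermediate two-hub trees exceed 0.5 — and reduces to
the original form when LN is read as a fraction of edges.  An
exhaustive check over all labeled trees on 4–6 nodes confirms
0 < TH ≤ 1.

## Statistics

Group differences use two-sided independent-sample t-tests with pooled
variance (the conventional reading of "independent t-test"; Welch is a
config option).  A Shapiro–Wilk screen per group × measure × band is
advisory: results are reported but the pipeline proceeds regardless,
as the t-test is the pre-declared analysis.  Bonferroni families
follow the analysis structure: within each band, the two measures of a
graph method (weighted cc/pl; binary cc/pl; MST leaf fraction/tree
hierarchy) form one family of 2; the binary sweep multiplies in its 15
densities (family of 30); global mean PLI stands alone.  Corrected
significance is declared at p < 0.01, with 0.01 ≤ p < 0.05 reported as
"marginal".  Edgewise maps use Benjamini–Hochberg FDR at 0.05 with
zero-variance edges flagged and excluded.

## The synthetic cohort generator

The generator emulates the *statistical situation* of a two-group
resting-state EEG study — band-specific lagged phase coupling, one
group with multiplicatively reduced coupling — not the biophysics of
EEG.  The model:

* Every channel owns one unit-variance carrier per configured band
  (white noise band-passed with the pipeline's own filters).
* A cohort-level layout (drawn once per seed, identical for all
  subjects) selects `fraction_of_pairs` of all channel pairs with
  probability ∝ h_i·h_j, where the hubness profile h is a fixed set of
  log-normal quantiles (`hub_concentration` = sd of log h, default 1.5)
  randomly assigned to channels.  The heavy-tailed profile is a design
  property: functional brain networks are hub-dominated, and hub
  structure is what gives the intact group's spanning tree its
  star-like, high-leaf-fraction backbone.  A uniform pair layout
  (hub_concentration = 0) produces trees statistically
  indistinguishable from random-weight MSTs in *both* groups and hence
  no recoverable tree-topology effect at realistic sample sizes.
* Each coupled pair is directed from its higher-hubness end; the
  target's band component is its own carrier plus
  `strength · u_e · c_source(t − δ_e)`, standardized to unit variance.
  `u_e` ~ U(1/3, 1) models heterogeneous connection strengths; the lag
  δ_e corresponds to a per-edge phase lag drawn from U(0.5, 1.5) ×
  the configured lag (default π/4 at the band center, implemented as a
  whole-sample shift, never 0).  The lag jitter matters: with one
  common lag, co-targets of a hub share their source component at
  *zero* relative lag, which PLI cannot see and which depresses their
  pairwise PLI; jittered lags turn that indirect coupling into weak
  but visible positive PLI, so global mean PLI increases monotonically
  with coupling strength as intended.
* Group 2 multiplies the coupling strength by `group_effect[band]`
  (default scenario: 0.5 in alpha).  Independent Gaussian broadband
  noise of sd `noise_sd` (default 1.0, i.e. 0 dB against the
  unit-variance band component) is added to every channel.

Determinism: one seed drives two separate RNG streams (layout, data),
so the coupled-pair ground truth is recoverable from the config alone
(`cohort_layout`, `coupled_pairs`) and two calls with the same config
are bit-identical.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: volume conduction and reference
effects (no zero-lag crosstalk between channels), 1/f background
spectra, artifacts (blinks, EMG, line noise), electrode geometry and
spatially structured coupling, non-stationarity, and any specific
neural dynamics.  Recovery results demonstrate that the pipeline
detects the kind of effect it is built for at the stated sizes; they do
not calibrate sensitivity on clinical EEG.

## Validation problem sizes

The package's own validation study (in `tests/test_acceptance.py`)
uses: a recovery cohort of 20 + 20 subjects, 32 channels, 60 s at
250 Hz, alpha coupling 0.9 halved in group 2, gamma coupling 0.9 in
both groups (seed 0) — alpha mean PLI and leaf fraction must be
significant at corrected p < 0.01 and no gamma measure may be; and 50
null cohorts (8 + 8 subjects, 16 channels, 20 s, coupling present, no
group effect) for type-I calibration, with the per-family rate of
corrected p < 0.01 held within binomial tolerance (±2.58 binomial sd)
of the nominal 0.01.  Oracle checks run at 6–8 nodes (triple-loop
clustering, Floyd–Warshall, path-enumeration betweenness) and 7 nodes
for exhaustive spanning-tree enumeration (7⁵ = 16 807 trees).

The recovery effect size of tree measures varies with the drawn
coupling layout: across layouts the leaf-fraction t-statistic at these
sizes typically falls between 3 and 6, occasionally lower for layouts
whose drawn pairs happen to under-use the hub profile.  Mean PLI and
the normalized weighted measures are far less layout-sensitive
(t ≈ 11–21).

## Known limitations

* PLI's finite-sample floor makes absolute connectivity values
  band-dependent (narrow bands sit higher); only contrasts are
  interpretable.
* The binary path length is degenerate at high densities (see above);
  it is reported but flagged.
* Surrogate normalization preserves only the weight multiset, not the
  degree sequence — the conventional choice for weight-reshuffled
  surrogates, but a different null than degree-preserving rewiring.
* Tree hierarchy of near-star trees is sensitive to single-edge
  changes at small N; at 32 channels its group test is noticeably
  noisier than leaf fraction's.
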