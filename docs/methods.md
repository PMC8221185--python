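# Methods

`dynmst` re-implements a dynamic brain-network analysis for trial-structured
multichannel electrophysiology: band-limited epochs are turned into per-trial
phase-coupling networks in sequential 100-ms windows, each network is reduced
to its maximum-spanning-tree backbone, tree topology is compared between two
experimental conditions through a dissimilarity-gated nonparametric testing
stack, and the selected topology measures are validated as single-trial
classification features. A synthetic-signal generator with planted coupling
topologies provides ground truth for every stage.

## Connectivity: phase lag index in short windows

Instantaneous phase comes from the analytic signal `z(t) = x(t) + i x~(t)`
(`x~` the Hilbert transform); both filtering and the Hilbert transform run on
the full −200..800 ms epoch, and the five post-stimulus windows
(0–100, …, 400–500 ms) are sliced from the phase array afterwards, so that
transform edge artifacts stay outside the analysed segment. The band filter
is a 4th-order Butterworth applied forward and backward (zero phase): PLI
consumes instantaneous phase, so any group delay would bias it.

The phase lag index of a channel pair is `|mean_k sgn(sin Δφ(t_k))|` with the
three-valued signum (`sgn(0) = 0`). Phase differences locked at exactly 0 or π
contribute nothing — this removes zero-lag synchronization, the signature of
volume conduction. With N samples of *independent* phase, E[PLI] ≈ √(2/(πN))
(≈ 0.08 at N = 100). Two caveats that matter at 100-ms windows:

* **Null bias for narrowband signals.** The phase difference of two
  independent band-limited processes decorrelates on the scale of the inverse
  bandwidth. Within a 100-ms window an alpha-band (4 Hz wide) phase
  difference barely moves, so single-trial null PLI is high (~0.85); even in
  the gamma band (15 Hz wide) it is ~0.5. The √(2/(πN)) null is reached only
  by phase series that decorrelate per sample. Condition comparisons remain
  valid — both conditions share the bias — but absolute single-trial PLI
  values in short windows must not be read as coupling strength.
* Sin values within ±1e−12 of zero are snapped to zero before the signum so
  that analytically zero-lag inputs behave deterministically.

## Tree backbone and measures

PLI is a similarity, so the backbone is the **maximum** spanning tree:
Kruskal over edges sorted by descending weight, ties broken by ascending
(i, j) for exact reproducibility. On N nodes the tree has m = N − 1 links.
Measures (normalizations chosen so values are comparable across tree sizes):

| measure | definition |
|---|---|
| degree (K), MaxK | node degree / m; maximum over nodes |
| leaf fraction Lf | (# degree-1 nodes) / m |
| diameter D | longest shortest path (hops) / m |
| eccentricity E | per-node max hop distance / m |
| betweenness BC, MaxBC | fraction of node pairs separated by the node, normalized by (N−1)(N−2)/2 |
| tree hierarchy Th | L / (2 · m · MaxBC), L the raw leaf count |
| mean edge PLI | mean of the m edge weights (regional coupling strength) |

Tree betweenness is computed in closed form (paths in a tree are unique:
BC(v) = C(N−1,2) − Σ_branches C(n_b,2), normalized), verified against the
Brandes algorithm in the test suite. The two extreme structures anchor
interpretation: a line has raw max degree 2, 2 leaves, diameter N−1
(chained, locally clustered processing); a star has raw max degree N−1,
N−1 leaves, diameter 2 (hub-mediated integration, short paths). Binarizing
the tree keeps the topology and all topological measures; the mean edge PLI
is always taken from the pre-binarization weights.

## Tree dissimilarity and the statistical gate

Two trees over the same nodes are compared through per-node neighbourhood
distance sums `S_k(i) = Σ_j 1/PLI(i,j)` over the direct tree neighbours j of
i; the score is the average log ratio `(1/N) Σ log10(S_n(i)/S_m(i))`. It is
zero on identity, antisymmetric, and invariant to rescaling all weights —
the reciprocal distance keeps the ratio scale-free, which is why `1/PLI` is
the default (`1 − PLI` is available behind a switch but breaks none of the
identities only by accident of symmetric examples). Each trial's tree is
scored against a **reference tree**: the maximum spanning tree of the
element-wise mean adjacency of the neutral ("scrambled") condition, computed
per (band, window) from the analysis subset only.

Testing is nonparametric throughout (two-sided Wilcoxon rank-sum; exact
enumeration when the pooled sample is ≤ 20 and tie-free, otherwise the
normal approximation with tie and continuity corrections), with
Benjamini–Hochberg step-up correction. The two-stage procedure:

1. **Gate.** Per (band, window) cell, compare the two conditions'
   dissimilarity scores; BH across the full band × window grid. Cells that
   fail carry no further tests.
2. **Selection.** In the gate-passing cells, test each global measure
   (D, Lf, MaxBC, MaxK, Th, mean edge PLI) and, per node, degree and
   betweenness. Each measure forms its own correction family spanning the
   *full* grid (× nodes for nodal measures) even when the gate admitted only
   a few cells — the gate can only make the correction stricter, never more
   lenient. Directions are reported as the sign of the median difference.

## Single-trial classification

Significant (measure, band, window[, node]) entries form the feature
manifest; each held-out trial's features are assembled in deterministic
(band, window, measure, node) order. The classifier is an RBF-kernel SVM
(C = 1, `gamma="scale"`; the kernel and hyperparameters are declared
defaults, not tuned) evaluated with stratified five-fold cross-validation,
5 repetitions: scaling statistics are fitted on training folds only,
decision values are pooled within a repetition for the ROC, and accuracy /
sensitivity / specificity / AUC are averaged over repetitions. Feature
selection happens on the analysis subset and classification on the disjoint
validation subset of the 70/30 stratified split, so the manifest is not
fitted to the evaluation trials. A raw time-segment baseline (concatenated,
optionally decimated amplitude samples from the occipito-temporal channels
P7, PO7, PO3, O1, POz, Oz, O2, PO4, PO8, P8, TP9, TP10) is provided for
comparison. Cross-validation is stratified at the trial level, pooled over
subjects, which can be optimistic if strong per-subject structure exists.

## Synthetic generator

The generator emulates the acquisition geometry of the emulated study —
63 channels named by the 10-10 montage, 1000 Hz, −200..800 ms epochs, three
conditions, five canonical bands — while controlling only what the analysis
actually measures: between-channel phase relations per (condition, band,
window) cell.

Construction per band and trial:

* every channel receives an independent **constant-modulus analytic
  carrier** whose phase trajectory comes from band-limited Gaussian noise
  (white noise → zero-phase Butterworth → Hilbert → envelope normalized).
  The envelope is normalized away deliberately: PLI is phase-only, and the
  Rayleigh fades of a complex Gaussian carrier would cause correlated
  coupling drop-outs on both channels of a pair;
* a planted coupling graph contributes a shared carrier: a breadth-first
  traversal accumulates each edge's target lag into a per-channel phase
  offset, and each node mixes the rotated shared carrier with its
  independent carrier at amplitude fraction `coupling_strength × edge
  weight` (variance preserving);
* **per-edge phase jitter** (independent narrowband processes, sd 0.6 rad by
  default) accumulates along each node's path from the component root, so
  phase coherence decays with graph distance. Without it a shared carrier
  makes every pair in a component equally phase-locked — the planted graph
  would be a clique in PLI terms and no tree topology could be recovered;
* the mixing coefficient is localized to the planted window with 30-ms
  cosine ramps placed just outside the window borders: the full analysis
  window stays coupled while the crossfade (which prevents spectral
  discontinuities) spills only a few attenuated milliseconds into the
  neighbours;
* broadband sensor noise (`noise_sd`, default 1.0 relative to the per-band
  unit-RMS oscillations) is added last.

Two planted-graph builders cover the extremes: `star_graph` (hub leads each
spoke by π/2, spoke signs alternating so the montage average — which the
common average reference subtracts — stays carrier-free) and `chain_graph`
(π/2 per link, making even-distance accumulated lags invisible to PLI while
the per-edge jitter decays odd-distance coherence).

What the generator does *not* emulate: realistic EEG spectra (1/f
background, alpha peaks), volume-conduction forward mixing, artifacts,
evoked transients, inter-subject variability (exposed as free parameters
rather than claimed). Passing recovery tests therefore demonstrates that the
pipeline recovers phase-coupling topology under controlled conditions, not
that it would detect any particular effect in real recordings.

### Validation study conditions

`synth.validation_study_config` freezes the planted study used by the
acceptance suite: 16 channels; star (face-like condition) versus chain
(ketch-like condition) planted in windows T2 and T3 of the beta (13–30 Hz)
and gamma (31–46 Hz) bands; an uncoupled scrambled condition as reference;
coupling strength 0.9; noise sd 1.0. Beta/gamma were chosen because a
planted 100-ms coupling window is only resolvable when the band's filter
memory (≈ 1/bandwidth) is shorter than the window; the ≤ 4 Hz-wide
delta/theta/alpha filters smear any 100-ms structure over several windows
at these settings. Problem sizes used by the validation suite: 10
repetitions × 200 trials/condition for gate recovery; one 200
trials/condition study to build the feature manifest and an independent 500
trials/class set for the cross-validated SVM; 100 repetitions × 60
trials/condition × 5×5 grid for the null false-discovery simulation.

## Numerical choices and degenerate inputs

* Kruskal ties: lexicographic (i, j) — exact ties are measure-zero on data
  but common in constructed tests.
* Rank-sum on two completely identical samples: p = 1 with a degenerate
  flag (the statistic carries no information) rather than an error.
* BH with a family larger than the tested set: adjusted p = p·m/rank with m
  the declared family size, monotonicity enforced, clipped to [0, 1].
* Dissimilarity with a zero-weight tree edge: error (1/PLI undefined) —
  zero-PLI edges can only enter a spanning tree if a connectivity estimate
  is degenerate, which deserves a failure, not a silent patch.
* All-zero signals: the analytic phase is undefined and raises.
* The stratified split computes per-condition counts as
  `round(fraction × n)` on the exact rational product (round-half-to-even),
  avoiding float artefacts at .5 boundaries.
* Every random draw in a pipeline run derives from the single configuration
  seed; regenerating with the same seed is bit-identical.

## Known limitations

* Short-window PLI bias (above): absolute PLI levels in 100-ms windows are
  bandwidth-dependent and inflated; only contrasts are interpretable.
* The dissimilarity gate inherits the FDR guarantee per family; nodal
  follow-ups are conditional on the gate and interpreted descriptively.
* Narrow bands cannot carry window-localized planted effects at these epoch
  lengths; the generator will accept such plans but recovery tests would be
  insensitive — a physics constraint, not a software one.
* The per-trial network uses N = 100 samples per window; tree estimates at
  63 channels from 100 samples are noisy, which is why condition-level
  inference pools hundreds of trials.
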