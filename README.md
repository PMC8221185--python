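# dynmst

Dynamic brain-network topology analysis for trial-structured multichannel
electrophysiology (EEG): phase-lag-index networks in sequential 100-ms
windows, maximum-spanning-tree backbones and their graph measures,
dissimilarity-gated nonparametric condition comparison, and single-trial
classification from the selected tree measures. A synthetic-signal
generator with planted coupling topologies makes every stage testable
without access to recordings.

## The method

For each trial, frequency band (delta/theta/alpha/beta/gamma) and 100-ms
post-stimulus window (T1–T5), a functional network is built from the
**phase lag index** between every channel pair,

    PLI = | (1/N) Σ_k sgn( sin(φ_a(t_k) − φ_b(t_k)) ) |,

with instantaneous phase from the Hilbert analytic signal. The PLI ignores
phase differences locked at 0 or π, making it robust to volume conduction.
Each network is reduced to its **maximum spanning tree** (Kruskal), the
unique-path backbone on which topology is compared without thresholding
bias: diameter D, leaf fraction L_f, maximum degree MaxK, maximum
betweenness MaxBC, tree hierarchy Th = L/(2·m·MaxBC), and the mean edge
PLI, bracketed by the line (D = N−1, two leaves) and star (D = 2, N−1
leaves) extremes.

Conditions are compared in two gated stages: per (band, window) cell, the
information-based tree dissimilarity `S_n/m = (1/N) Σ_i log10(S_n(i)/S_m(i))`
of each trial's tree against a reference tree (built from the neutral
condition's mean adjacency) is tested between conditions with the Wilcoxon
rank-sum test, FDR-corrected across the grid; only passing cells are tested
measure-by-measure (and node-by-node for degree and betweenness), again
FDR-corrected. Significant measures become features for an RBF-SVM
evaluated with repeated stratified five-fold cross-validation on a held-out
trial subset.

## Worked example

The bundled configuration plants a star coupling graph (hub = channel 0)
for the "face" condition and a chain graph for the "ketch" condition in
window T2 of the beta and gamma bands, with an uncoupled "scrambled"
reference condition — 150 trials per condition, 16 channels:

```bash
dynmst run-all --config examples/config.yaml --out runs/demo
```

The run directory then contains one inspectable artifact per stage
(epoch archive, PLI stacks, measure tables, gate and selection CSVs,
feature manifest, classification report). On this configuration the
dissimilarity gate recovers exactly the two planted cells:

```
    band  window         p_raw  direction     p_adj  significant
1   beta       2  3.217234e-07         -1  0.000003         True
6  gamma       2  9.433063e-04         -1  0.004717         True
```

and feature selection keeps 25 of 76 tested (measure, band, window[, node])
rows — leaf fraction and maximum degree higher for the star condition,
diameter lower. The classifier trained on those features separates the two
conditions' held-out trials (45 per class in this small demo) at:

```
{'accuracy': 0.791, 'sensitivity': 0.733, 'specificity': 0.849,
 'auc': 0.887, 'n_trials': 90, 'n_features': 25}
```

Accuracy grows with trial count; the validation suite's larger study
(500 trials per class) reaches ≈ 0.93 accuracy / 0.99 AUC
(`tests/test_acceptance.py`).

The same stages are available as a library:

```python
import dynmst
from dynmst.synth import validation_study_config

epochs = dynmst.generate_dataset(validation_study_config(seed=1))
ref = dynmst.common_average_reference(epochs)
band = dynmst.bandpass(ref, (31.0, 46.0))
phases = dynmst.instantaneous_phase(band.data)
window = dynmst.window_slices(band)[1]              # T2: 100-200 ms
pli = dynmst.pli_matrix_stack(phases[:, :, window])  # trials x 16 x 16
tree = dynmst.max_spanning_tree(pli[0], band.channel_labels)
print(dynmst.mst_measures(tree).as_dict())
```

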