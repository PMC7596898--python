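"""Sparse-representation classification: dictionary, L1 coding, residuals.

Training features become unit-norm dictionary columns grouped by class; a
test feature is coded as a sparse combination of columns (basis pursuit)
and assigned the class whose columns reconstruct it with smallest residual.
"""

import numpy as np

import sparsebci as sb
from sparsebci.csp import FeatureVector

rec, _ = sb.generate(sb.SimConfig(n_trials_per_class=40, seed=0))
epochs = sb.bandpass(sb.segment_epochs(rec, 3.0), 8.0, 15.0)
split = sb.shuffle_split(len(epochs), epochs.labels, n_test=20, seed=0)

model = sb.fit_csp(epochs.subset(split.train_indices), 8)
Xtr, ytr = sb.feature_matrix(model, epochs.subset(split.train_indices))
Xte, yte = sb.feature_matrix(model, epochs.subset(split.test_indices))

d = sb.build_dictionary([FeatureVector(v, int(l)) for v, l in zip(Xtr, ytr)])
print(f"dictionary: {d.m} x {d.N} ({d.N} training atoms, redundant since m < N)")

code = sb.solve_l1(d, FeatureVector(Xte[0] / np.linalg.norm(Xte[0])))
nnz = np.sum(np.abs(code.x_hat) > 1e-6)
print(f"first test trial: {nnz}/{d.N} nonzero coefficients, "
      f"residuals per class = {np.round(code.residuals, 4)}, "
      f"predicted class {code.predicted_class} (true {yte[0]})")

out = sb.classify_src(d, [FeatureVector(v) for v in Xte])
acc = 100.0 * np.mean([p == t for (p, _), t in zip(out, yte)])
print(f"held-out SRC accuracy: {acc:.1f}% on {len(yte)} trials")
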