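"""Train the fast-compression residual CNN on sparse codes.

The sparse coefficient vectors from the dictionary stage are the network's
input sequence; training codes are computed leave-one-column-out so no trial
sees its own atom.  The network compresses the input with a stride-3
convolution, refines it through three residual modules, and classifies with
a softmax head.
"""

import numpy as np

import sparsebci as sb
from sparsebci import nn
from sparsebci.csp import FeatureVector
from sparsebci.evaluation import _atom_columns

rec, _ = sb.generate(sb.SimConfig(n_trials_per_class=40, seed=0))
epochs = sb.bandpass(sb.segment_epochs(rec, 3.0), 8.0, 15.0)
split = sb.shuffle_split(len(epochs), epochs.labels, n_test=20, seed=0)

model = sb.fit_csp(epochs.subset(split.train_indices), 8)
Xtr, ytr = sb.feature_matrix(model, epochs.subset(split.train_indices))
Xte, yte = sb.feature_matrix(model, epochs.subset(split.test_indices))
d = sb.build_dictionary([FeatureVector(v, int(l)) for v, l in zip(Xtr, ytr)])

codes_tr = sb.sparse_features(d, [FeatureVector(v) for v in Xtr],
                              exclude_columns=_atom_columns(ytr))
codes_te = sb.sparse_features(d, [FeatureVector(v) for v in Xte])
print(f"sparse codes: train {codes_tr.shape}, test {codes_te.shape}")

cfg = nn.NetworkConfig(input_length=d.N, seed=0)
net = nn.build_network(cfg)
print(f"network: {net.parameter_count()} parameters, layers: {net.layer_inventory()}")

nn.train(net, codes_tr, ytr)
probs, pred = nn.predict(net, codes_te)
acc = 100.0 * np.mean(pred == yte)
print(f"final training loss {net.history[-1]['train_loss']:.4f}, "
      f"accuracy {net.history[-1]['train_acc']:.3f}")
print(f"held-out accuracy: {acc:.1f}% on {len(yte)} trials; "
      f"first-trial probabilities {np.round(probs[0], 3)}")
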