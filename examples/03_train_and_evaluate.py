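"""Train the three-strategy residual-network ensemble and evaluate it.

This example uses a small dataset and a narrow channel schedule so it runs
in about two minutes on a laptop CPU; scale `n_per_class`, the model config
and `epochs` up for real experiments.
"""

import numpy as np

import ramanres as rr
from ramanres.resnet import ModelConfig
from ramanres.train import TrainConfig, train_ensemble

cfg = rr.SimConfig(n_per_class=150, seed=1)
dataset, labels = rr.simulate_dataset(cfg)
matrix = rr.preprocess_pipeline(dataset, labels=labels)

model_cfg = ModelConfig.compact(seed=3)     # stem 8, 6 stages, cap 32
train_cfg = TrainConfig(epochs=12, learning_rate=1e-3, batch_size=64, seed=5)

ensemble, (tr, va, te) = train_ensemble(matrix, model_cfg, train_cfg)
test = matrix.subset(te)

probs = rr.ensemble_predict(ensemble, test)
report = rr.evaluate_model(lambda v: probs, test)
print(f"test spectra: {test.n}")
print(f"ensemble  accuracy {report.accuracy:.3f}  AUC {report.auc:.3f}  "
      f"F1 {report.f1:.3f}")
print("confusion matrix (rows true normal/tumor):")
print(report.confusion_matrix())

for name, p in ensemble.member_probabilities(test).items():
    rep = rr.evaluate_model(lambda v, p=p: p, test)
    print(f"member {name:<10} accuracy {rep.accuracy:.3f}")

# the ensemble is the exact 0.8/0.1/0.1 convex combination of its members
members = ensemble.member_probabilities(test)
manual = 0.8 * members["original"] + 0.1 * members["intensify"] + 0.1 * members["split"]
print("mixing identity holds:", bool(np.allclose(manual, probs)))
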