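"""Localize the spectral evidence a trained network uses, via 1-D Grad-CAM,
and annotate the activated Raman-shift regions with tissue components.
"""

import numpy as np

import ramanres as rr
from ramanres.resnet import ModelConfig
from ramanres.train import TrainConfig

cfg = rr.SimConfig(n_per_class=150, seed=1)
dataset, labels = rr.simulate_dataset(cfg)
matrix = rr.preprocess_pipeline(dataset, labels=labels)

train_cfg = TrainConfig(epochs=12, learning_rate=1e-3, batch_size=64, seed=5)
train_m, val_m, test_m = rr.split_dataset(matrix, train_cfg)
model = rr.train(
    rr.build_model(ModelConfig.compact(seed=3)), train_m, val_m, train_cfg
)

row = test_m.values[test_m.labels == 1][0]
cam = rr.grad_cam(model, row, target_class=1, grid=test_m.grid)
print(f"relevance profile: {cam.relevance.size} channels in [0, 1]")
print("activated regions (relevance >= 0.5):")
for lo, hi in cam.activated_regions:
    print(f"  {lo:7.1f} - {hi:7.1f} 1/cm")

annotations = rr.assign_peaks(cam.activated_regions)
for ann in annotations:
    lo, hi = ann["region"]
    comps = {a["component"] for a in ann["assignments"]}
    print(f"region {lo:.0f}-{hi:.0f} 1/cm -> {', '.join(sorted(comps)) or 'no known band'}")

truth = sorted(rr.ground_truth_channels(cfg))
axis = cfg.grid_axis()
hits = sum(1 for ch in truth if any(lo <= axis[ch] <= hi for lo, hi in cam.activated_regions))
print(f"ground-truth channels inside activated regions: {hits}/{len(truth)}")
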