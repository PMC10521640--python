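# ramanres

Tumor-vs-normal classification of Raman spectra with a one-dimensional
residual convolutional network — for chemometricians and biomedical
spectroscopists who want a complete, reproducible reference pipeline:
synthetic spectrum generation, spectral preprocessing, augmentation, a
1D-ResNet with a three-strategy weighted ensemble, evaluation metrics, and
Grad-CAM interpretation of what the network looks at.

Raman spectra of resected colorectal tissue differ only slightly between
tumor and normal samples: the same bands appear in both classes and the
class information sits in small intensity differences at a few
wavenumbers. The pipeline implemented here takes spectra on a 385-1545
cm^-1 grid (1024 channels after resampling), cleans them (asymmetric
least-squares baseline removal, Savitzky-Golay denoising, per-spectrum
min-max normalization), and classifies them with a pre-activation residual
network whose blocks are two [BN -> ReLU -> dropout -> conv(1x3)] sets with
a shortcut, H(X) = F(X) + X, downsampling by stride-2 stages until a
1024-channel, length-1 feature map feeds a sigmoid head. Three strategies —
the original spectra, spectra with intensified main peaks, and two
lower-shift windows ([0,512) and [128,640) channels) — train separate
members that are mixed 8:1:1:

    p = 0.8 p_original + 0.1 p_intensify + 0.1 p_split

Training uses Adam with class-weighted binary cross-entropy
(w1 = n/2n_pos, w0 = n/2n_neg) and an 80/10/10 stratified split;
evaluation reports accuracy, precision, recall, F1 and trapezoidal-rule
AUC (equal to the Mann-Whitney statistic with half tie credit). Grad-CAM
relevance maps localize the spectral evidence and are annotated against a
shipped colorectal-tissue peak-assignment table (15 bands, 497-1447
cm^-1). The network, its backward pass and Adam are implemented in NumPy
inside the package; no deep-learning framework is required.

Because clinical Raman datasets are rarely public, the package includes a
first-class synthetic generator that emulates the acquisition (Gaussian
bands at the assignment positions, fluorescence background, three averaged
scans per sample, 26-patient structure, slight class differences on four
bands) so every stage is testable end to end.

## Worked example

```bash
python examples/03_train_and_evaluate.py
```

generates 300 synthetic spectra, trains the three-strategy ensemble
(compact channel schedule, 12 epochs) and prints:

```
test spectra: 30
ensemble  accuracy 1.000  AUC 1.000  F1 1.000
confusion matrix (rows true normal/tumor):
[[15  0]
 [ 0 15]]
member original   accuracy 0.967
member intensify  accuracy 1.000
member split      accuracy 1.000
mixing identity holds: True
```

The synthetic task is separable by design, so all three strategy members
approach perfect held-out accuracy within a few epochs and the 8:1:1
mixture corrects the original member's single residual error.
`examples/04_interpret_with_gradcam.py` then shows Grad-CAM recovering the
planted class signal: its activated regions include all four bands the
generator made discriminative (936, 986, 1328, 1447 cm^-1), plus secondary
regions at the shared bands whose *relative* height the per-spectrum
normalization ties to the class:

```
activated regions (relevance >= 0.5):
    592.5 -   612.9 1/cm
    ...
    928.1 -   950.8 1/cm
    978.0 -  1027.9 1/cm
   1319.3 -  1344.3 1/cm
   1438.4 -  1463.4 1/cm
region 928-951 1/cm -> Polysaccharides
region 978-1028 1/cm -> Glucose, Ribose
region 1319-1344 1/cm -> DNA/RNA
region 1438-1463 1/cm -> Collagen
ground-truth channels inside activated regions: 57/57
```

Other examples: `01_simulate_and_inspect.py` (generator structure),
`02_preprocess_spectra.py` (cleaning-chain guarantees),
`05_command_line_pipeline.py` (the YAML-driven CLI).

## Command line

```bash
ramanres simulate   --config run.yaml --out runs/demo --seed 7
ramanres preprocess --config run.yaml --out runs/demo
ramanres train      --config run.yaml --out runs/demo
ramanres evaluate   --config run.yaml --out runs/demo
ramanres explain    --config run.yaml --out runs/demo
# or all five:
ramanres run-all    --config run.yaml --out runs/demo --seed 7
```

One YAML file configures every stage (`simulate:`, `preprocess:`,
`augment:`, `intensify:`, `model:`, `train:`, `ensemble:` keys); a single
`global_seed` derives all module seeds. Logs go to stderr, data to files.

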