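# surgseg

Unsupervised temporal segmentation of robot-assisted surgery procedures from
**system data only** — surgeon-side-console kinematics (SSC), patient-side
instrument/camera kinematics (SI) and binary system events (EVT) of a da
Vinci-class platform — into clinically relevant tasks, without video and
without labels.

The package is built around a multi-task porcine training session treated as
one continuous *pseudo-procedure*: five tasks (two-handed robotic suturing,
uterine horn dissection, suspensary ligament dissection, running robotic
suturing, rectal artery skeletonization and clipping) performed back to back.
Because such recordings are proprietary, `surgseg` ships a synthetic
generator that reproduces their statistical skeleton — per-task duration
distributions, smooth task-specific kinematic dynamics and task-specific
event-activation rates — so the entire pipeline is testable offline.

## What it computes

Given a multivariate series `T ∈ R^{d×N}`, frames are vector-quantized per
trial with k-means into `N_s` symbols and re-embedded as symbol centroids,
then compared through a Gaussian frame kernel
`f_ij = exp(−‖t_i − t_j‖² / 2σ²)`. Four temporal clustering algorithms are
provided:

- **ACA** (aligned cluster analysis): kernel k-means over temporal segments
  `Q_m` with lengths in `[l_min, l_max]`, minimizing
  `J(G, s) = Σ_k Σ_m g_{k,m} D²(Q_m, z_k)` where `D²` expands through the
  dynamic time alignment kernel (DTAK) `τ_ij` between segments; boundaries
  are re-optimized each iteration by dynamic programming.
- **HACA**: ACA run at a fine temporal scale, then re-run over the resulting
  segments using the DTAK matrix between them as a reduced kernel.
- **GMM** and **spectral clustering**: per-frame baselines whose label runs
  are read out as segmentations.

Predictions are scored frame-wise: the confusion matrix `C` between
predicted clusters and true tasks is matched with the Hungarian algorithm,
`accuracy = max_P tr(CP) / N`, plus per-task precision/recall/F1 and a
proportional-duration baseline (boundaries predicted from average normalized
task durations alone).

## Worked example

```python
import numpy as np
from surgseg import (GeneratorConfig, generate_trial, downsample,
                     downsample_segmentation, build_features, frame_kernel,
                     ACAConfig, haca, run_with_restarts, evaluate)

gen = GeneratorConfig(time_scale=0.13, seed=0)          # ~1000 s pseudo-procedure
rec, truth = generate_trial(gen, seed=0)
rec1 = downsample(rec, target_hz=1.0)                   # 50 Hz -> 1 Hz
truth1 = downsample_segmentation(truth, window=50)

feats = build_features(rec1, "si+evt", n_symbols=15, seed=0)
F = frame_kernel(feats)                                 # median-heuristic sigma
cfg = ACAConfig(K=5, l_min=3, l_max=30)
pred = run_with_restarts(lambda seed: haca(F, cfg, seed=seed), {}, n_init=5, base_seed=0)

scores = evaluate(pred, truth1)
print(f"N = {feats.N} frames at 1 Hz, M = {pred.M} segments")
print(f"restart energies: {np.round(pred.meta['energies'], 3)}")
print(f"accuracy = {scores['accuracy']:.3f}, macro-F1 = {scores['macro_f1']:.3f}")
print("recall per task:", np.round(scores['recall'], 3))
```

prints

```
N = 1063 frames at 1 Hz, M = 54 segments
restart energies: [7.298 3.233 3.232 3.242 3.312]
accuracy = 0.996, macro-F1 = 0.996
recall per task: [1.    1.    0.991 1.    0.994]
```

The five restart energies show the minimum-energy protocol at work (the
first initialization converged to a poor local optimum and was discarded);
99.6 % of the 1063 one-second frames end up in the correct task after the
optimal cluster-to-task matching.

A command-line interface wraps the same pipeline:

```bash
surgseg generate --n-trials 9 --time-scale 0.13 --seed 0 --out data/
surgseg segment --trial data/trial-0.h5 --algo haca --features si+evt --k 5 --out pred.csv
surgseg evaluate --pred pred.csv --truth truth.csv --report report.json
surgseg experiment --config exp.json     # full algorithms x feature-sets sweep
```

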