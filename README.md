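# eitbladder

Simulation-to-classification pipeline for **electrical-impedance
bladder-state detection**: can a supervised classifier tell a *full*
bladder from a *not-full* one using raw boundary-voltage measurements
from a pelvic electrode belt, without reconstructing an image?

The package is aimed at researchers in bioimpedance-based physiological
monitoring. It provides:

* a parametric pelvis/bladder **EIT forward simulator** — elliptical-
  cylinder FEM domain (2-D electrode-plane reduction or full 3-D
  tetrahedra), a volume-parameterised ellipsoid bladder with a fixed
  bottom position (the bladder ascends as it fills), a 32-electrode
  skip-4 stimulation pattern producing 928-measurement frames;
* an **SNR-controlled Gaussian noise model** (20–80 dB) with seeded,
  reproducible replicate streams;
* **factor-grid dataset builders** for the study's test cases TC1–TC4
  (volume × urine conductivity × pelvic boundary × SNR), fullness
  labelling and stratified 10-fold splits;
* **classifiers and evaluation** — linear SVM, cubic SVM and cosine
   10-NN on standardised frames, with sensitivity, specificity, balanced
  accuracy and per-factor misclassification analysis;
* CSV/HDF5 frame archives, an import path for externally recorded
  (phantom-style) frames, and an `eitbladder` CLI.

## Model in brief

On a domain $\Omega$ with conductivity $\sigma$ (0.2 S/m background,
urine conductivity $\sigma_u \in [0.5, 3.5]$ S/m inside the bladder) the
forward problem is

$$\nabla\cdot(\sigma\nabla u)=0 \ \text{in } \Omega,$$

driven by ±5 mA through electrode pairs $(i,\ i+5 \bmod 32)$; each
injection retains the 29 offset-5 measurement pairs not touching an
injection electrode, so a frame is $u \in \mathbb{R}^{928}$. Noisy
replicates are $u_i + \max|u|\,\eta_i$ with $\eta$ Gaussian, calibrated
so the realised SNR $20\log_{10}(\lVert u\rVert/\lVert u_{noise}-u
\rVert)$ matches the stated level. A frame is labelled *full* iff its
volume $\ge$ 300 ml (configurable). Classifiers report sensitivity
(correct-on-full), specificity (correct-on-not-full) and balanced
accuracy $=(\text{sens}+\text{spec})/2$ over stratified 10-fold splits.

## Worked example

```python
import numpy as np
from eitbladder import (IdealFrameSimulator, ClassifierSpec, build_testcase,
                        make_folds, run_10fold, tc_spec)
from eitbladder.classify import misclassification_by_factor

sim = IdealFrameSimulator(domain="2d")          # electrode-plane reduction
spec = tc_spec(1)                                # 14 volumes, 99 noisy frames
ds = build_testcase(spec, snr_db=20.0, seed=1, simulator=sim)
print(ds.n_obs, ds.class_counts())

folds = make_folds(ds, 10, seed=1)
res = run_10fold(ds, folds, [ClassifierSpec("linear_svm")])
m = res["linear_svm"].metrics
print(f"sens {100*m.mean_sensitivity:.2f}%  spec {100*m.mean_specificity:.2f}%"
      f"  acc {100*m.mean_accuracy:.2f}%")
hist = misclassification_by_factor(res["linear_svm"], ds, "volume")
print(hist[hist > 0].round(2).to_dict())
```

Output:

```
1400 {'not_full': 700, 'full': 700}
sens 98.71%  spec 98.29%  acc 98.50%
{240: 0.07, 280: 0.79, 300: 0.64}
```

1,400 observations (one ideal + 99 noisy frames for each of 14 bladder
volumes) are split 50/50 by the 300 ml threshold. Even at the
harshest noise level (20 dB) the linear SVM stays above 98% balanced
accuracy, and the few errors sit at 240–300 ml — immediately around the
fullness threshold, where adjacent volumes differ least. At 60–80 dB
the problem becomes perfectly separable (100%/100% for every
classifier).

The same pipeline scales to the multi-factor grids: `tc_spec(2)` adds
13 urine conductivities, `tc_spec(3)` six pelvic boundaries,
`tc_spec(4)` a fully withheld "realistic scenario" grid, and
`tc_spec("360")` re-labels a shifted grid at a 360 ml threshold.

From the shell:

```bash
eitbladder build-dataset --tc 1 --snr 60 --seed 1 --n-noisy 9 --out tc1.h5
eitbladder train-eval --dataset tc1.h5 --classifier linear_svm --out metrics/
eitbladder report --metrics metrics/
```

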