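# drcsi — diffusion–relaxation correlation MRI spectra and myelin water maps

`drcsi` reconstructs non-parametric relaxation/diffusion spectra from
multidimensional brain MRI and derives myelin-water fraction (MWF) maps.
It is aimed at quantitative-MRI researchers working with diffusion-weighted
inversion-recovery spin-echo (DW-IR-SE) acquisitions that vary two of the
three encoding parameters — inversion time TI, echo time TE, b-value — on an
8 × 8 grid (64 contrasts), giving joint sensitivity to T1–T2, T1–D or T2–D.

## Model

Each voxel's real-valued signal is a non-negative mixture over Q candidate
water pools on a linearly spaced (T1, T2, D) grid:

```
M_p = Σ_q f_q · (1 − 2·exp(−TI_p/T1_q) + exp(−TR/T1_q)) · exp(−TE_p/T2_q) · exp(−b_p·D_q),   f ≥ 0
```

Estimating the spectrum F from M = K F is an ill-conditioned inverse
problem (Q = 3600 unknowns from P = 64 signals in 2D).  `drcsi` solves it
in two convex steps:

1. **1D subproblems** (Q = 60 from P = 8, the contrasts with the other
   parameter at its minimum) with spatially regularized non-negative least
   squares via ADMM (neighbor-difference penalty, λ_s1D = 0.5);
2. **2D correlation problem** with product-space Douglas–Rachford
   splitting, combining the data term, a reduced spatial penalty
   (λ_s2D = 0.01), non-negativity, and L1 penalties (λ_m = 10³) that keep
   the 2D solution's marginals close to the 1D solutions.

Compartmental signal fractions (myelin water, intra/extra-cellular water,
CSF) are obtained by thresholded integration of the spectra and normalized
so MWF + f_IC/EC + f_CSF = 1.  A digital brain phantom (concentric
CSF/GM/WM regions, three-pool mixtures, magnitude noise with polarity
loss) makes the whole chain testable end to end; user data enter as 4D
NIfTI volumes with a JSON sidecar table of (TI, TE, b, directions).

See `docs/methods.md` for the full model, solver and phantom description.

## Worked example

```python
import numpy as np
from drcsi import (RunConfig, run_pipeline)

result = run_pipeline(RunConfig(seed=1))        # 48×48 phantom, TI×TE preset, SNR 100
print(result.results["1D-T1"].summary(masks=result.masks))
```

```
Spectral inversion results
==========================
method:      admm (ADMM)
grid:        T1 (60 = 60 components)
contrasts:   P = 8
voxels:      N = 1396
iterations:  818 (converged: True)
weights:     lambda_s1D = 0.5
mean RMSE:   0.00357674

tissue  mean_mwf  sd_mwf  median_mwf  n_voxels
   CSF    0.0000  0.0000      0.0000       112
    GM    0.0804  0.0134      0.0766       504
    WM    0.1313  0.0033      0.1313       780
```

The 1D T1 spectra recover the phantom's myelin-water signal fraction:
~13% median MWF in white matter versus a 14% spectral ground truth (the
difference is the echo-time weighting at TE = 4.5 ms), ~7.7% in gray matter
(6% ground truth, inflated by spatial smoothing against the neighboring WM
ring) and 0% in CSF, with the GM < WM ordering that myelin mapping relies
on.  `result.fractions["2D"]` holds the corresponding maps from the 2D
T1–T2 correlation spectra, and `result.rmse` the per-voxel fit errors.

The same workflow is available from the shell:

```
drcsi run-all -w out/                 # simulate → preprocess → fit1d → fit2d → maps
drcsi simulate -w out/ --protocol t1t2 --seed 1   # or step by step
drcsi preprocess -w out/ && drcsi fit1d -w out/ && drcsi fit2d -w out/
drcsi maps -w out/ && drcsi report -w out/
```

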