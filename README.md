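# msdager

Joint k-q reconstruction of highly undersampled multi-shell diffusion MRI
with a Gaussian-process prior over q-space, plus the simulation and
evaluation machinery to study it. For MRI methods researchers who want a
self-contained, testable implementation of GP-regularized multi-band
reconstruction at accelerations beyond the parallel-imaging limit.

## The method in brief

A diffusion-weighted volume at q-space location (g, b) shares most of its
information with its angular neighbors and with the matching directions on
other shells. `msdager` models the per-voxel signal across the Nd
diffusion directions as a Gaussian process

    u ~ N(mu, Sigma),    Sigma_ij = lambda * C_theta(theta_ij; a) * C_b(b_i, b_j; l)

with a compact-support spherical covariance in (antipodal) angle and a
squared-exponential covariance in log b, per-shell noise variances on the
diagonal, and hyperparameters fitted from the data by restricted maximum
likelihood, separately for white and gray matter. The GP prediction then
regularizes a joint reconstruction of all volumes:

    u = argmin_u  sum_j 1/(2 sigma_k,j^2) || Omega_j F S P_j u_j - d_j ||^2
                + 1/2 sum_v (u_v - mu_v)^H Sigma^-1 (u_v - mu_v)

where Omega_j is the blipped-CAIPI undersampling pattern of volume j (SMS
treated as 3D kz encoding), S the coil sensitivities, P_j the shot-to-shot
phase error, and sigma_k^2 the k-space noise variance per shell estimated
with a Rician-aware variance-stabilizing (VST) approach. Every q-space
neighborhood is assigned maximally diverse k-space patterns so neighbors
contribute complementary data. The alternation of noise estimation,
hyperparameter fitting, GP prediction and joint solve is described in
`docs/methods.md`.

The single-shell ablation (`ss-dager`) decouples the shells; plain
`sense` is the per-volume CG-SENSE baseline.

## Worked example

Simulate a two-shell ball-and-stick phantom (36 directions, 8 coils,
SMS=4 x R=3, SNR 20), reconstruct, and evaluate:

```python
from msdager.io import RunConfig
from msdager.pipeline import run_study

config = RunConfig(simulator={"grid": [4, 36, 32], "n_per_shell": 18,
                              "snr": 20.0},
                   reconstruction={"outer_iters": 4})
results = run_study(config, seed=7, methods=("sense", "ms-dager"))
for method in ("sense", "ms-dager"):
    m = results["methods"][method]
    print(f"{method:9s} nRMSE={m['nrmse_object']:.3f} "
          f"cross-shell ratio decrease={m['ratio_decrease_percent']:+.1f}%")
```

prints (exact values depend on the seed):

```
sense     nRMSE=0.621 cross-shell ratio decrease=+16.4%
ms-dager  nRMSE=0.530 cross-shell ratio decrease=+11.1%
```

meaning: at 12-fold undersampling with 8 coils the per-volume SENSE
baseline is dominated by aliasing and noise (nRMSE 0.62 against the
noise-free ground truth over the object), the GP-regularized joint
reconstruction removes a substantial part of that error, and its
white-matter b1000/b2000 intensity ratio sits closer to the ground truth's
(the ratio-decrease metric quantifies cross-shell smoothing plus the
Rician noise floor; smaller is better).

The same pipeline is scriptable from the shell:

```
msdager simulate --config cfg.json --seed 7 --out sim/
msdager design --R 3 --SMS 4 --bvals sim/truth.bval --bvecs sim/truth.bvec --out assignment.json
msdager reconstruct --data sim/data.h5 --method ms-dager --out dwi.nii.gz
msdager evaluate --recon dwi.nii.gz --truth sim/truth.nii.gz --mask sim/tissue_label.npy --out metrics.json
```

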