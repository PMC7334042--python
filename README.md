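# qbold — model-based oxygen extraction mapping from ASE MRI

`qbold` estimates brain oxygenation parameters from **asymmetric spin echo
(ASE)** MRI signals using the **streamlined quantitative BOLD (sqBOLD)**
model family. It is aimed at MR physicists and neuroimaging researchers who
want to map, voxel by voxel:

- **OEF** — the oxygen extraction fraction of the capillary bed,
- **DBV** — the deoxygenated (venous) blood volume fraction,
- **R2′** — the reversible transverse relaxation rate, R2\* − R2.

## The model

Venous vessels are modelled as randomly oriented cylinders whose
susceptibility offset is proportional to OEF. In the static dephasing
regime the extravascular (tissue) signal is

    St(t) = exp(−R2t·t) · exp(−DBV · I(δω·t)),
    I(x)  = ∫₀¹ (2+u)·√(1−u)/(3u²) · (1 − J₀(1.5·x·u)) du,

with the characteristic frequency

    δω = (4/3)·π · γ·B₀ · Δχ₀ · Hct · OEF.

Under ASE the refocusing pulse is shifted by τ/2 at fixed TE, and the
integral is replaced for fitting by its asymptotic branches (quadratic for
|τ| < tc = κ/δω, linear-exponential above, with calibrated transition
constant κ ≈ 1.76); in the long-τ regime R2′ = DBV·δω, so OEF can be
recovered from fitted (R2′, DBV) via

    OEF = 3·R2′ / (4π · γ·B₀ · Δχ₀ · Hct · DBV).

A second, intravascular compartment (venous blood, weighted by the
apparent blood volume ζ′ = m_b·n_b·DBV) can be added; the default blood
model treats intravascular dephasing in the motional-narrowing regime, and
monoexponential and Fresnel ("powder") alternatives are provided.

Three estimation engines share these forward models:

| engine | idea |
|---|---|
| `infer_ls` | classic log-linear sqBOLD fit (slope/intercept of ln S over long τ) and bounded non-linear least squares |
| `infer_grid` | exhaustive grid-search posterior over (OEF, DBV) or (R2′, DBV) with marginal summaries — the parameter-separability analysis |
| `infer_vb` | variational Bayes: Gaussian approximate posterior, Gamma noise precision, free-energy tracking, optional iterative spatial priors over 6-connected neighbours |

A simulator (`simulate`) reproduces the reference synthetic study — a
50×50 OEF×DBV grid (20–70% × 0.3–15%), 24 spin-echo offsets from −28 to
+64 ms, Gaussian noise at 7 SNR levels between 5 and 500 — and small 3-D
NIfTI phantoms for testing spatial regularization.

## Worked example

Simulate one grey-matter voxel (OEF 40%, DBV 3%, so R2′ = 4.26 s⁻¹) with
noise at SNR 100, then fit it with the log-linear estimator and with
variational Bayes on the two-compartment model:

```python
from qbold import (AcquisitionProtocol, BloodCompartment, TissuePhysiology,
                   simulate_signal, add_noise, fit_loglinear, vb_fit,
                   oef_from_r2p)

proto = AcquisitionProtocol()           # TE 74 ms, 24 tau values
blood = BloodCompartment()
phys  = TissuePhysiology(oef=0.40, dbv=0.03)

noisy = add_noise(simulate_signal(phys, blood, proto), snr=100, rng=3)

ll = fit_loglinear(noisy, proto)
print(f"log-linear : R2'={ll.r2p:.2f}  DBV={100*ll.dbv:.1f}%  "
      f"OEF={100*ll.oef:.0f}%  ({ll.n_points} points)")

fit = vb_fit(noisy, model="2c", blood=blood, proto=proto)
oef = oef_from_r2p(fit["r2p"], fit["dbv"], 0.40, proto)
print(f"VB 2C      : R2'={fit['r2p']:.2f}±{fit.sd[0]:.2f}  "
      f"DBV={100*fit['dbv']:.1f}±{100*fit.sd[1]:.1f}%  OEF={100*oef:.0f}%")
```

Output:

```
log-linear : R2'=4.00  DBV=2.1%  OEF=53%  (14 points)
VB 2C      : R2'=4.10±0.20  DBV=2.6±1.1%  OEF=44%
```

Both estimators recover R2′ well (truth 4.26 s⁻¹); DBV — and through it
OEF — is far less certain, which the VB posterior makes explicit
(DBV 2.6 ± 1.1%). This OEF–DBV collinearity at realistic SNR is exactly
what the grid-search separability analysis quantifies, and why fitting is
performed in (R2′, DBV) rather than (OEF, DBV) coordinates.

Voxelwise maps from a 4-D NIfTI volume, with spatial regularization:

```sh
qbold fit ase.nii --mask gm_mask.nii --tau-file tau.json \
      --engine vb --model 2c --spatial --out-dir maps/
```

writes `r2p.nii`, `dbv.nii`, `oef.nii`, their SD maps, a free-energy map
and a JSON run report (priors, κ, convergence, fraction of voxels with
OEF > 100%).

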