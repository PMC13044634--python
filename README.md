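# corrspec

Correlation-spectroscopy analysis of molecular transport for
fluorescence microscopists: **FCS** (fluorescence correlation
spectroscopy, photon traces from a fixed confocal volume) and **RICS**
(raster image correlation spectroscopy, raster-scanned image stacks
whose scan timing encodes temporal lags). The package covers the whole
workflow — quality screening, autocorrelation estimation, diffusion
model fitting under realistic error models, Bayesian model selection,
and spatial parameter mapping — plus a Brownian-dynamics simulator that
generates data with known ground truth for validation.

## The model

Intensity fluctuations `δI` of diffusing emitters are summarized by the
autocorrelation function. Temporal (FCS):

    G(τ) = ⟨δI(t) δI(t+τ)⟩ / ⟨I⟩²

Spatial (RICS), with pixel lags (ξ, ψ) mapped to lag times
`τ(ξ,ψ) = ξ·t_pix + ψ·t_line` and to sample-frame displacements through
the scan-angle rotation:

    G(ξ, ψ) = ⟨δI(x,y) δI(x+ξ, y+ψ)⟩ / ⟨I⟩²

Both are fitted with the anisotropic free-diffusion model under a 3-D
Gaussian PSF with 1/e² waists ω (or a measured PSF grid):

    G(Δ, τ) = 1/(V_eff⟨C⟩) · ∏ᵢ ωᵢ/√(4 DCᵢ τ + ωᵢ²) · exp(−Δᵢ²/(4 DCᵢ τ + ωᵢ²))

with `V_eff = π^{3/2} ωx ωy ωz`, optional two-component mixtures,
and a triplet (dark-state) factor `1 + TSA/(1−TSA)·e^{−τ/τ_T}`.
Parameters are estimated by bound-constrained nonlinear least squares or
by nested-sampling Bayesian inference under three error models — OLS
(uniform), WLS (per-point σ), GLS (full empirical lag covariance Σ) —
with the log-evidence `log Z` for model comparison. See
`docs/methods.md` for conventions and numerical choices.

## Worked example

Simulate a single FCS trace (100 particles in a 2.5 × 2.5 × 7 μm³ box,
DC = 100 μm²/s, 1 μs bins), correlate and fit it:

```python
import corrspec as cs

cfg = cs.SimConfig(n_particles=100, box=(2.5, 2.5, 7.0),
                   dc_true=(100.0,) * 3, duration=10.0, dt=1e-6, seed=42)
trace = cs.simulate_fcs_trace(cfg)

acf = cs.acf_fcs(trace, window=(1.25, 8.75), max_lag=0.02)
acf = cs.crop_and_downsample(acf, drop_first=1, log_bins=100)

psf = cs.GaussianPsf(0.3, 0.3, 1.1)
post = cs.fit_bayes(acf, cs.ModelSpec(kind="iso1"), psf, seed=3)
print(f"DC = {post.mean('dc'):.1f} ± {post.std('dc'):.1f} um^2/s")
print(f"C  = {post.mean('c'):.2f} ± {post.std('c'):.2f} nM")
print(f"log Z = {post.log_z:.1f} ± {post.log_z_err:.2f}")
```

Output from this exact run:

```
DC = 99.3 ± 1.8 um^2/s
C  = 3.87 ± 0.02 nM
log Z = 239.9 ± 0.26
```

The posterior-mean diffusion coefficient recovers the simulation truth
(100 μm²/s) within its uncertainty, and the concentration lands within
2% of the 3.80 nM implied by 100 particles in the box. The same API fits raster
stacks (`simulate_rics_stack`, `acf_rics`), joint multi-angle
anisotropic models, and cohort-mean ACFs under GLS with
`estimate_covariance`.

A `corrspec` command-line tool wraps the library for scripted runs:

```sh
corrspec simulate-trace --out run.h5 --duration 10 --seed 42
corrspec acf --input run.h5 --out run.h5 --max-lag 0.02 --drop-first 1 --log-bins 100
corrspec fit --input run.h5 --out post.nc --framework bayes --errors ols
corrspec plot --input run.h5 --kind acf_log --out acf
```

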