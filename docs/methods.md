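# Methods

`corrspec` analyses fluorescence-fluctuation measurements of molecular
transport: point FCS (fluorescence correlation spectroscopy) and RICS
(raster image correlation spectroscopy). This note records the models the
package implements, the estimator and numerical conventions it commits
to, and what its synthetic-data generator does and does not emulate.

## Correlation estimators

**Temporal ACF (FCS).** For binned photon counts `I(t)` the package
computes `G(τ) = ⟨δI(t) δI(t+τ)⟩ / ⟨I⟩²` with `δI = I − ⟨I⟩`, where `⟨I⟩`
is the mean over the user-selected analysis window (not the whole
record): restricting the window excludes unstable segments and the
normalization must be consistent with that choice. The numerator is
evaluated by zero-padded FFT with the biased `1/M` normalization
(`M` = window length); the biased form is the conventional fluctuation
estimator and differs from the unbiased one by `O(τ/M)`, negligible at
the lag ranges fitted here. A direct `O(N·L)` reference implementation
(`acf_fcs_direct`) is kept for validation; the two agree to ≤1e−10
relative error on traces up to 4096 bins in the test suite.

**Spatial ACF (RICS).** `G(ξ, ψ)` is the spatial correlation of `δI`
averaged over all overlapping pixel pairs at each lag, computed per frame
by zero-padded FFT and averaged over frames; the per-point uncertainty is
the SEM across frames. The scan timing maps pixel lags to lag times,
`τ(ξ, ψ) = ξ·t_pix + ψ·t_line`, with `t_line` including the flyback dead
time. Two normalization modes exist:

- `mean_normalize` — subtract each frame's spatial mean, divide by the
  squared mean (solution data). Caveat: per-frame mean subtraction forces
  the correlation summed over all lags to zero, depressing every lag by
  about `Σ_lags G / n_pixels`. This is invisible at ordinary precision
  but matters in high-precision fits of weak decays.
- `background_subtract` — subtract a group-average image (acquisition
  slot average, or simply the across-frame mean) from each frame. The
  denominator is selectable: the variance of the background-subtracted
  signal (`G(0,0) ≈ 1`; the default, matching common practice for
  structured cellular backgrounds), the squared variance (a literal
  reading of an ambiguous convention, kept as an explicit switch), or
  the squared mean of the background image, which preserves the
  `1/(V_eff⟨C⟩)` amplitude semantics and is what the package's own
  high-precision synthetic RICS analyses use, because it avoids the
  per-frame zero-sum bias entirely (cost: a multiplicative `1 − 1/n_frames`
  shrinkage absorbed by the fitted concentration).

**Log-binning.** Dense linear-lag ACFs are averaged within logarithmic
lag bins before fitting. Because `G` is convex in `τ`, the bin mean of
the data exceeds the model evaluated at the bin-mean lag; fitting would
then see a spurious fast component (it mimics triplet blinking). The
package therefore stores up to 7 representative source lags per bin and
averages the *model* over the same bins during fitting, making data and
model see identical binning.

## Diffusion and photophysics models

The PSF is a 3-D Gaussian ellipsoid `exp(−2x²/ωx² − 2y²/ωy² − 2z²/ωz²)`
(waists are 1/e² radii; a global scale factor in [0, 2] multiplies all
three) or a measured voxel grid. The effective volume is
`V_eff = [∫PSF]²/∫PSF²` (= `π^{3/2}ωxωyωz` for the Gaussian).

The anisotropic free-diffusion correlation for sample-frame displacement
`Δ` and lag `τ` is

```
G(Δ, τ) = 1/(V_eff ⟨C⟩) · ∏_{i∈{x,y,z}} ωi/√(4 DCi τ + ωi²) · exp(−Δi²/(4 DCi τ + ωi²))
```

**Amplitude convention.** The per-axis factor is written so that
`G(0, 0) = 1/(V_eff⟨C⟩)` exactly. A formulation that keeps both a
`1/V_eff` prefactor and dimensional `1/√(π(4DCτ+ω²))` axis factors
double-counts the volume normalization; the convention here is the
standard fluctuation result and is what makes the fitted concentration
physically interpretable (tested: fitted C matches simulation truth).
No additional geometric γ-factor is applied. Concentrations are handled
internally in molecules/μm³ and exposed in nM (1 nM = 0.6022
molecules/μm³).

Two-component transport is the `f : (1−f)` mixture of two such decays
sharing `⟨C⟩`. Triplet (dark-state) blinking multiplies `G` by
`1 + TSA/(1−TSA)·exp(−τ/τ_T)`. Scan geometry enters through the
z-rotation of pixel displacements `(ξ s_ξ, ψ s_ψ, ζ s_ζ)` by the scan
angle α. Point FCS is the `Δ = 0` special case. Anisotropic fits offer
`full` (DCx, DCy, DCz), `uniaxial` (DCy = DCz) and `quasi2d` (DCz = 0)
conventions; planar raster data constrain DCz only through the axial PSF
extent, so `uniaxial` is the default.

**Measured PSF.** For a PSF sampled on a voxel grid,
`G(Δ,τ) = ∫∫ PSF(r)·K(r′−r,τ)·PSF(r′−Δ) / (⟨C⟩ [∫PSF]²)` with `K` the
free-diffusion Green's function (per-axis variance `2·DCi·τ`). This is
evaluated as a per-axis Gaussian blur of the grid followed by an inner
product with the Δ-shifted grid (trilinear interpolation off-grid; blur
σ under half a voxel falls back to the unblurred grid with a warning).
Against a Gaussian-sampled grid the numerical model matches the closed
form within 2% on the tested (τ, Δ) lattice; at `τ = 0, Δ = 0` it equals
`1/(V_eff_grid⟨C⟩)` identically. Trilinear interpolation and voxel size
are the dominant tolerance contributors.

**Bead-stack processing.** Bead images are localized above a threshold,
cropped (target half-width 5 fitted waists per axis, clipped to the
stack), aligned at sub-voxel precision by the least-squares Gaussian
centroid, averaged, and refitted for the waists. Per-stack median
background subtraction is on by default (camera offset) and switchable.
Sampling coarser than 40 nm lateral / 100 nm axial triggers a warning.
Voxel downsampling is block-mean pooling with trailing partial blocks
dropped (floor division: 35 → 17 at factor 2, → 11 at factor 3).

## Error models and fitting

All fits minimize or sample `χ²(θ) = rᵀWr`, `r = y − f(θ)`:
OLS (`W = I`), WLS (`W = diag(1/σi²)`, σ from frame/trace SEMs) and GLS
(`W = Σ⁻¹` with the empirical lag covariance
`Σij = 1/(N−1) Σk [Gk(τi)−Ḡ(τi)][Gk(τj)−Ḡ(τj)]`). Σ is symmetrized and
Cholesky-validated, with diagonal jitter escalating from `1e−10·trace/n`
to `1e−8·mean diagonal` before a hard error — never a silent
pseudo-inverse. Reliable estimation wants far more traces than lag
points (a warning fires below 3×). GLS is refused for raster (RICS)
data, where frame-to-frame replicates cannot support a stable lag
covariance. The GLS fit of a cohort-mean ACF deliberately uses the
single-trace Σ (not Σ/N): this is the convention that makes the
posterior reflect trace-to-trace variability rather than the formal
error of the mean, and it reproduces the characteristic
OLS < WLS < GLS posterior-width ordering.

**NLS.** Bound-constrained trust-region least squares on the whitened
residuals, from a deterministic multi-start: prior-box center plus
per-parameter offsets (half-box on a linear scale; log-spaced for the
triplet relaxation time, whose prior spans six decades and is
unreachable from linear starts). Complex models additionally warm-start
from the nested simpler fit (single-component / no-triplet) with a small
deterministic grid over the extra parameters — two-component and
triplet models otherwise collapse into local optima. WLS/GLS fits also
warm-start from the OLS solution. Parameter covariance comes from the
whitened Jacobian; for OLS the residual variance is estimated post hoc
as `S(θ̂)/(n−p)`, and WLS covariance is scaled by the reduced χ² to
absorb misspecified per-point σ (GLS is trusted as given). Fits landing
on prior bounds are flagged with a warning. Residual transforms follow
the error model: raw (OLS), standardized `ri/σi` (WLS), decorrelated
`L⁻¹r` with `Σ = LLᵀ` (GLS); the GLS χ² equals the squared norm of the
decorrelated residuals by construction.

**Bayesian inference.** Likelihoods are Gaussian and match the error
model: inferred common σ (OLS; log-uniform prior spanning
`[1e−6, 1e2] ×` the data scale, jointly sampled — a proper likelihood
needs a noise scale), fixed per-point σ (WLS), or the full Σ with its
determinant (GLS). Priors are independent uniforms on the default
bounds: DC 0–5000 μm²/s, C 0–1000 nM, TSA 0–1, τ_T 0.01–10⁴ μs, PSF
scale 0–2, fraction f 0–1; two-component models are parameterized as
(DC1, ΔDC > 0) so DC1 < DC2 holds by construction and label switching
cannot occur.

Sampling uses an in-package static nested sampler: classic
shrinking-volume bookkeeping with the worst live point replaced by
likelihood-constrained slice sampling along live-covariance-shaped
directions. Two reinforcements matter for these posteriors, whose
high-likelihood region can occupy a ~1e−8 fraction of the prior box
(e.g. sub-nM concentrations under a 0–1000 nM prior):

- scale-spanning positive parameters (DCs, ΔDC, C, τ_T) are *sampled*
  from a power-law density concentrated toward the lower bound
  (`θ = lo + span·u³`), and the evidence and posterior weights are
  importance-corrected back to the declared uniform priors — exact in
  expectation, it only reallocates sampling effort;
- termination (remaining-evidence fraction < dlogz = 0.05) is not
  allowed before 15 e-folds of prior-volume shrinkage, so a
  plateau-dominated likelihood cannot trigger a premature stop before
  the basin is found.

Defaults: 300 live points, `max(5, 2·ndim)` slice moves per
replacement. The reported evidence uncertainty is `√(H/n_live)`. On a
conjugate Gaussian-mean toy with analytic evidence the sampler is
within 3 reported uncertainties (tested); evidence comparisons are only
allowed between runs sharing one error model, and Δlog Z is graded
indistinguishable (<1), positive (1–3), strong (3–5), very strong (>5).

Goodness of fit reports SSR, χ² and `χ²_ν = χ²/(n−p)`; for posteriors
these are evaluated at the median posterior parameters. Nested point
fits can be compared by the F-test,
`F = [(χ²_s−χ²_c)/(p_c−p_s)]/[χ²_c/(n−p_c)]`.

## Screening and mapping

Stability screening drops the shortest leading prefix of traces/frames
whose remaining-sequence mean still deviates from the tail-half mean by
more than a set fraction (default 10%) — a scripted stand-in for the
visual inspection this step classically is, exposed as a parameter; an
explicit index list overrides it. Exclusion reports list every item as
kept or excluded-with-reason. The DC–C pre-analysis fits every
individual ACF with the simplest compatible model (isotropic
single-component, OLS) — a screening statistic, not an estimate — and
excludes items outside explicit DC/C ranges or beyond 5 MAD of the
cohort median, which automates the scatter-plot-based manual exclusion
for scripted runs.

Sector mapping splits images into `sector_self` (disjoint tiling),
`larger_self` (overlapping larger areas centered on sector centers) or
`pair` (sector-size reference inside a concentric larger area)
configurations, with centers evenly spaced so extreme regions touch but
never cross the image borders, ties rounded toward the image center.
Each sector gets its own spatial ACF and NLS fit (OLS default; WLS from
frame SEMs); failed sectors are masked with reasons, never
interpolated. Map rows follow image rows (row 0 at top), centers in μm
from the image origin. Joint multi-condition fits share the physical
parameters {DCs, f, C, TSA, τ_T, PSF scale} while each condition keeps
its own scan geometry; the angular summary flags anisotropy when
|DCx − DCy| exceeds twice the combined uncertainty.

## Synthetic-data generator

Free Brownian diffusion of point emitters in a periodic box (periodic
wrap keeps concentration exactly uniform; the box should be ≳5 PSF
waists per axis or periodic images of the focal volume overlap — a
warning fires). Per step each particle takes an independent Gaussian
displacement of per-axis std `√(2·DCi·dt)`. Photon counts are Poisson
draws with mean `dt·(background + brightness·Σk PSF(rk − r_focus))`,
the PSF peak-normalized and the intensity taken at the bin start (no
sub-bin integration; `dt` is far below the diffusion time at all
default settings, and the sampled-process ACF equals the continuous one
at the sampled lags regardless). Brightness defaults to 30 000 counts/s
per molecule at the PSF peak — a typical single-fluorophore detection
rate; it puts the default single-trace run near 13 kcounts/s.
Raster stacks sample the same emission model along the scan trajectory
(pixel (j, i) at `t = j·t_line + i·t_pix`, focus offset rotated by α),
with particles diffusing continuously through dwells and flyback and no
photons recorded during flyback. Ground truth and seed are stored in the
output metadata. A numba kernel integrates the per-particle walk (the
numpy path is kept for trajectory output and environments without
numba; both paths consume the same random stream and produce identical
traces). Simulations are bit-reproducible given the seed.

Default conditions are the standard synthetic studies: single-trace —
100 particles in 2.5 × 2.5 × 7 μm³, DC = 100 μm²/s, dt = 1 μs, Gaussian
PSF ω_xy = 0.3 μm / ω_z = 1.1 μm; multitrace — 25 particles in
8 × 8 × 12 μm³, DC = 20 μm²/s. The generator does **not** emulate
triplet blinking (models fit TSA = 0 data only), photobleaching,
detector afterpulsing/dead time, anomalous diffusion, or spatially
varying mobility — heterogeneity fixtures are composed by tiling
independent simulations. Passing recovery tests therefore demonstrate
estimator and inference correctness under ideal free diffusion with
shot noise, not robustness to those artifacts.

## Desk-scale study sizes

The validation suite and the reproduction script run reduced versions
of the full studies, chosen once as the package's own desk-scale
conditions: the single trace is 10 s (analysis window at the same
1/8–7/8 record fractions as the full 80 s study), and the multitrace
cohort is 48 traces of 20 s at dt = 5 μs with 20 log-binned lag points
up to 0.1 s. Trace length matters more than cohort size here: with the
single-trace Σ convention the likelihood's information content scales
with trace duration, while the cohort size mainly stabilizes the Σ
estimate (kept above twice the number of lag points, with the estimator
warning acknowledged). Short-trace estimators carry a small positive DC
bias from window-mean subtraction (a few percent at 10 s), which decays
as 1/duration and is visible in the single-trace recovery numbers.
Anisotropy checks use 3 scan angles × 4 independent replicates and take
the replicate spread, not the single-fit standard errors, as the
uncertainty — WLS fit errors understate configuration-to-configuration
variability in raster data.

## Known limitations

- No shrinkage covariance estimation; the empirical Σ needs generous
  cohorts.
- No flow/active-transport or anomalous-diffusion terms; no
  two-channel cross-correlation (FCCS).
- GLS (and hence the most reliable evidence comparisons) is unavailable
  for RICS.
- The nested sampler is single-threaded and static; posteriors wider
  than ~8 parameters or strongly multimodal evidence surfaces warrant
  raising `n_live`/`n_slices` (the single-trace OLS triplet comparison
  in the tests does exactly that).
- Measured-PSF fitting cost grows with grid size; downsampled grids
  (factors 2–3) trade a monotone amplitude drift for speed.
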