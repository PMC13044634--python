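"""Forward correlation models for FCS and RICS.

Single- and two-component anisotropic free diffusion under a 3-D Gaussian
PSF, a multiplicative triplet (dark-state) blinking factor, scan-angle
rotation of pixel displacements into the sample frame, and a numerical
model for an arbitrary measured PSF grid.

Amplitude convention: G(Δ=0, τ=0) = 1/(V_eff·⟨C⟩), i.e. the per-axis
lateral/axial decay factor is ωᵢ/√(4·DCᵢ·τ + ωᵢ²) and the 1/V_eff
prefactor carries the volume dimension.  This is the standard fluctuation
normalization that makes the fitted concentration recoverable through
Eq. V_eff = π^{3/2}ωxωyωz.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .datatypes import DiffusionParams, GaussianPsf, PsfGrid, ScanGeometry
from .psf import v_eff, v_eff_grid


def rotate_displacement(xi, psi, zeta, geom: ScanGeometry) -> np.ndarray:
    """Map pixel displacements (ξ, ψ, ζ) to sample-frame Δ = (Δx, Δy, Δz).

    Applies the z-rotation by the scan angle α to the physical pixel
    offsets (ξ·s_ξ, ψ·s_ψ, ζ·s_ζ).  Arrays broadcast; returns (..., 3) μm.
    """
    xi = np.asarray(xi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    u = xi * geom.s_xi
    v = psi * geom.s_psi
    w = zeta * (geom.s_zeta or 0.0)
    a = np.deg2rad(geom.alpha)
    dx = np.cos(a) * u - np.sin(a) * v
    dy = np.sin(a) * u + np.cos(a) * v
    return np.stack(np.broadcast_arrays(dx, dy, w), axis=-1)


def triplet_factor(tau, tsa: float, tau_t: float):
    """Multiplicative dark-state factor 1 + TSA/(1−TSA)·exp(−τ/τ_T)."""
    if not 0 <= tsa < 1:
        raise ValueError("TSA must lie in [0, 1)")
    if tsa == 0:
        return np.ones_like(np.asarray(tau, dtype=float))
    if tau_t <= 0:
        raise ValueError("tau_t must be positive when TSA > 0")
    tau = np.asarray(tau, dtype=float)
    return 1.0 + tsa / (1.0 - tsa) * np.exp(-tau / tau_t)


def _component(delta: np.ndarray, tau: np.ndarray, dc, waists) -> np.ndarray:
    """Per-axis product ∏ ωᵢ/√(4DCᵢτ+ωᵢ²) · exp(−Δᵢ²/(4DCᵢτ+ωᵢ²))."""
    dc = np.asarray(dc, dtype=float)
    denom = 4.0 * dc * tau[..., None] + waists ** 2   # (..., 3)
    return np.prod(waists / np.sqrt(denom) * np.exp(-delta ** 2 / denom),
                   axis=-1)


def g_gaussian(delta, tau, params: DiffusionParams, psf: GaussianPsf):
    """Spatiotemporal ACF G(Δ, τ) under the Gaussian-ellipsoid PSF.

    ``delta`` has trailing axis 3 (sample-frame μm); broadcasts against
    ``tau`` (s).  Two-component kinds mix the component decays with
    fraction ``f``; the triplet factor multiplies the result.
    """
    waists = psf.waists
    if min(waists) <= 0:
        raise ValueError("nonpositive effective waist")
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    if delta.shape[-1] != 3:
        raise ValueError("delta must have a trailing axis of length 3")
    tau = np.asarray(tau, dtype=float)
    amp = 1.0 / (v_eff(psf) * params.c_mean)
    decay = _component(delta, np.broadcast_to(tau, delta.shape[:-1]),
                       params.dc, waists)
    if params.kind in ("iso2", "aniso2"):
        decay2 = _component(delta, np.broadcast_to(tau, delta.shape[:-1]),
                            params.dc2, waists)
        decay = params.f * decay + (1.0 - params.f) * decay2
    out = amp * decay * triplet_factor(np.broadcast_to(tau, decay.shape),
                                       params.tsa, params.tau_t)
    return out


def g_fcs(tau, params: DiffusionParams, psf: GaussianPsf):
    """Purely temporal ACF (point FCS): G(Δ=0, τ)."""
    tau = np.asarray(tau, dtype=float)
    zero = np.zeros(tau.shape + (3,))
    return g_gaussian(zero, tau, params, psf)


# ---------------------------------------------------------------------------
# Measured-PSF numerical model
# ---------------------------------------------------------------------------

def _blur_overlap(grid: PsfGrid, delta: np.ndarray, dc, tau: float) -> float:
    """∫ PSF(r)·[K_τ ⋆ PSF](r − Δ) dV on the voxel grid.

    K_τ is the free-diffusion propagator with per-axis variance 2·DCᵢ·τ.
    The blurred grid is shifted by Δ with trilinear interpolation.
    """
    vox = np.asarray(grid.voxel)
    sig_um = np.sqrt(2.0 * np.asarray(dc, dtype=float) * tau)
    sig_vox = sig_um / vox
    if np.any((sig_vox > 0) & (sig_vox < 0.5)):
        warnings.warn("diffusion blur below half a voxel; using the "
                      "unblurred grid for sub-voxel axes", stacklevel=3)
        sig_vox = np.where(sig_vox < 0.5, 0.0, sig_vox)
    blurred = ndimage.gaussian_filter(grid.values, sigma=sig_vox,
                                      mode="constant", cval=0.0)
    shift_vox = np.asarray(delta, dtype=float) / vox
    if np.any(np.abs(shift_vox) > np.asarray(grid.values.shape)):
        raise ValueError("displacement outside the PSF grid support")
    # inner product Σ_u PSF(u)·B(u+Δ): shift the blurred grid by −Δ
    shifted = ndimage.shift(blurred, -shift_vox, order=1, mode="constant",
                            cval=0.0)
    return float((grid.values * shifted).sum() * grid.voxel_volume)


def g_measured(delta, tau, params: DiffusionParams, psf: PsfGrid):
    """G(Δ, τ) for a measured PSF grid.

    G = ∫∫ PSF(r)·K(r′−r, τ)·PSF(r′−Δ) d³r d³r′ / (⟨C⟩·[∫PSF dV]²),
    evaluated as a per-axis Gaussian blur of the grid followed by an inner
    product with the Δ-shifted grid.  At τ=0, Δ=0 this reduces exactly to
    1/(V_eff_grid·⟨C⟩).  Triplet factor and two-component mixing as in
    :func:`g_gaussian`.
    """
    delta = np.atleast_2d(np.asarray(delta, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if delta.shape[-1] != 3:
        raise ValueError("delta must have a trailing axis of length 3")
    if delta.shape[0] == 1 and tau.size > 1:
        delta = np.broadcast_to(delta, (tau.size, 3))
    if tau.size == 1 and delta.shape[0] > 1:
        tau = np.broadcast_to(tau, (delta.shape[0],))
    out = np.empty(tau.size)
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for i, (d, t) in enumerate(zip(delta, tau)):
            num = _blur_overlap(psf, d, params.dc, t)
            if params.kind in ("iso2", "aniso2"):
                num2 = _blur_overlap(psf, d, params.dc2, t)
                num = params.f * num + (1.0 - params.f) * num2
            out[i] = num
    norm_total = (psf.values.sum() * psf.voxel_volume) ** 2 * params.c_mean
    g = out / norm_total * triplet_factor(tau, params.tsa, params.tau_t)
    return g if g.size > 1 else float(g[0])
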