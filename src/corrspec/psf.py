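"""PSF representations: Gaussian ellipsoid, effective volume, measured
3-D PSF processing from bead stacks, and voxel downsampling.

The effective focal volume V_eff = [∫PSF dV]² / ∫PSF² dV sets the zero-lag
correlation amplitude G(0) = 1/(V_eff·⟨C⟩); for the Gaussian ellipsoid with
1/e² waists ω it has the closed form π^{3/2}·ωx·ωy·ωz.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize

from .datatypes import GaussianPsf, PsfGrid

# acquisition sampling considered adequate for bead-based PSF measurement
ADEQUATE_LATERAL_VOXEL = 0.040   # μm
ADEQUATE_AXIAL_VOXEL = 0.100     # μm


def v_eff(psf: GaussianPsf) -> float:
    """Effective focal volume of a Gaussian PSF: π^{3/2}·∏(scale·ωᵢ), μm³."""
    wx, wy, wz = psf.waists
    return float(np.pi ** 1.5 * wx * wy * wz)


def _grid_axes(grid: PsfGrid):
    """Physical coordinates of the voxel centers, centered on the grid."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * v
        for n, v in zip(grid.values.shape, grid.voxel)
    ]


def v_eff_grid(grid: PsfGrid, warn_support: bool = True) -> float:
    """Riemann-sum effective volume of a sampled PSF, μm³."""
    vals = grid.values
    if warn_support:
        edge = max(vals[0].max(), vals[-1].max(),
                   vals[:, 0].max(), vals[:, -1].max(),
                   vals[:, :, 0].max(), vals[:, :, -1].max())
        if edge >= 0.01 * vals.max():
            warnings.warn("PSF grid edges exceed 1% of the peak; the grid may "
                          "not cover the PSF support", stacklevel=2)
    dv = grid.voxel_volume
    s1 = vals.sum() * dv
    s2 = (vals ** 2).sum() * dv
    return float(s1 ** 2 / s2)


def sample_gaussian_grid(psf: GaussianPsf, voxel, half_extent) -> PsfGrid:
    """Sample the Gaussian ellipsoid on a regular voxel grid (test utility)."""
    voxel = np.broadcast_to(np.asarray(voxel, dtype=float), (3,))
    half = np.broadcast_to(np.asarray(half_extent, dtype=float), (3,))
    w = psf.waists
    axes = [np.arange(-h, h + 0.5 * v, v) for h, v in zip(half, voxel)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    vals = np.exp(-2 * (x / w[0]) ** 2 - 2 * (y / w[1]) ** 2 - 2 * (z / w[2]) ** 2)
    return PsfGrid(values=vals, voxel=tuple(voxel))


# ---------------------------------------------------------------------------
# Gaussian fitting of sampled PSFs
# ---------------------------------------------------------------------------

def fit_gaussian(grid: PsfGrid):
    """Least-squares fit of the Gaussian ellipsoid to a sampled PSF.

    Returns (GaussianPsf, centroid) with the centroid in μm relative to the
    grid center.  Amplitude is fitted too (and discarded) so that
    peak-normalization does not bias the waists.
    """
    ax = _grid_axes(grid)
    x, y, z = np.meshgrid(*ax, indexing="ij")
    data = grid.values.ravel()
    w0 = [max(0.05, 2 * v) for v in grid.voxel]

    def model(theta):
        a, cx, cy, cz, wx, wy, wz = theta
        return a * np.exp(-2 * ((x - cx) / wx) ** 2
                          - 2 * ((y - cy) / wy) ** 2
                          - 2 * ((z - cz) / wz) ** 2).ravel()

    # moment-based initialization
    tot = data.sum()
    c0 = [float((v.ravel() * data).sum() / tot) for v in (x, y, z)]
    var = [max(float(((v.ravel() - c) ** 2 * data).sum() / tot), 1e-6)
           for v, c in zip((x, y, z), c0)]
    w_init = [max(2 * np.sqrt(s), wlo / 2) for s, wlo in zip(var, w0)]
    theta0 = [data.max(), *c0, *w_init]
    lo = [0, *(c - 10 * w for c, w in zip(c0, w_init)), 1e-4, 1e-4, 1e-4]
    hi = [np.inf, *(c + 10 * w for c, w in zip(c0, w_init)), np.inf, np.inf, np.inf]
    res = optimize.least_squares(lambda t: model(t) - data, theta0,
                                 bounds=(lo, hi))
    a, cx, cy, cz, wx, wy, wz = res.x
    return GaussianPsf(w_x=wx, w_y=wy, w_z=wz), np.array([cx, cy, cz])


# ---------------------------------------------------------------------------
# Bead-stack processing
# ---------------------------------------------------------------------------

def _shift_trilinear(vals: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    """Shift a 3-D array by a fractional voxel offset (linear interpolation,
    zero fill outside)."""
    from scipy import ndimage
    return ndimage.shift(vals, -shift_vox, order=1, mode="constant", cval=0.0)


def build_psf_from_beads(stacks: list, threshold: float = 0.3,
                         min_separation_vox: int = 8,
                         subtract_background: bool = True,
                         half_width_waists: float = 5.0):
    """Average well-separated bead images into one PSF and fit its waists.

    Beads are localized as local maxima above ``threshold``·max in each
    stack, a sub-volume is cut around each, the Gaussian-fit centroid is
    used to align sub-volumes at sub-voxel precision, and the aligned
    volumes are averaged.  Returns ``(PsfGrid, GaussianPsf)``.

    Per-stack median background subtraction is applied by default (camera
    offset); switch off with ``subtract_background=False``.
    """
    if not stacks:
        raise ValueError("need at least one bead stack")
    voxel = stacks[0].voxel
    lat = max(voxel[0], voxel[1])
    if lat > ADEQUATE_LATERAL_VOXEL + 1e-12 or voxel[2] > ADEQUATE_AXIAL_VOXEL + 1e-12:
        warnings.warn(
            "voxel sampling coarser than 40 nm lateral / 100 nm axial; "
            "bead-based waist estimates may be biased", stacklevel=2)

    aligned, shapes = [], []
    for grid in stacks:
        vals = grid.values.copy()
        if subtract_background:
            vals = np.clip(vals - np.median(vals), 0.0, None)
        peak = vals.max()
        if peak <= 0:
            raise ValueError("bead stack has no signal above background")
        # greedy local-maximum search above threshold
        cand = np.argwhere(vals >= threshold * peak)
        if cand.size == 0:
            raise ValueError("no bead above threshold")
        centers = []
        for idx in cand[np.argsort(-vals[tuple(cand.T)])]:
            if all(np.max(np.abs(idx - c)) >= min_separation_vox for c in centers):
                # reject candidates that merely ride the shoulder of an
                # accepted bead but are genuinely separate maxima
                centers.append(idx)
        for c in centers:
            # two-pass crop: provisional window for a first waist estimate,
            # then the definitive window at half_width_waists x the waist
            hw = np.full(3, max(4, min_separation_vox), dtype=int)
            for _ in range(2):
                lo = np.maximum(c - hw, 0)
                hi = np.minimum(c + hw + 1, np.asarray(vals.shape))
                if np.any(hi - lo < 5):
                    sub = None
                    break  # too close to the stack border
                sub = vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                sub_grid = PsfGrid(values=sub, voxel=voxel)
                fitted, centroid = fit_gaussian(sub_grid)
                # asymmetric clipping is fine: the centroid shift below
                # re-centers the bead in the averaged frame
                hw = np.maximum(
                    np.ceil(half_width_waists * fitted.waists
                            / np.asarray(voxel)).astype(int), 3)
            if sub is None:
                continue
            shift_vox = centroid / np.asarray(voxel)
            aligned.append(_shift_trilinear(sub_grid.values, shift_vox))
            shapes.append(sub.shape)
    if not aligned:
        raise ValueError("no usable bead found (all too close to borders?)")
    shape = tuple(np.min(shapes, axis=0))
    acc = np.zeros(shape)
    for a in aligned:
        off = [(s - t) // 2 for s, t in zip(a.shape, shape)]
        acc += a[off[0]:off[0] + shape[0], off[1]:off[1] + shape[1],
                 off[2]:off[2] + shape[2]]
    avg = PsfGrid(values=acc / len(aligned), voxel=voxel,
                  attrs={"n_beads": len(aligned)})
    fitted, _ = fit_gaussian(avg)
    return avg, fitted


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample_psf(grid: PsfGrid, factors) -> PsfGrid:
    """Block-mean pooling by integer factors; voxel sizes multiply.

    Trailing voxels that do not fill a complete block are dropped (floor
    division of the shape), so e.g. 35 voxels at factor 2 give 17.
    """
    factors = tuple(int(f) for f in np.broadcast_to(factors, (3,)))
    if min(factors) < 1:
        raise ValueError("factors must be integers >= 1")
    vals = grid.values
    if any(f > n for f, n in zip(factors, vals.shape)):
        raise ValueError("downsample factor exceeds grid size")
    n0, n1, n2 = (n // f for n, f in zip(vals.shape, factors))
    f0, f1, f2 = factors
    trimmed = vals[:n0 * f0, :n1 * f1, :n2 * f2]
    pooled = trimmed.reshape(n0, f0, n1, f1, n2, f2).mean(axis=(1, 3, 5))
    return PsfGrid(values=pooled,
                   voxel=tuple(v * f for v, f in zip(grid.voxel, factors)),
                   attrs=dict(grid.attrs))
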