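"""Autocorrelation estimation for FCS traces and RICS image stacks.

Temporal estimator: G(τ) = ⟨δI(t)δI(t+τ)⟩ / ⟨I⟩², with δI = I − ⟨I⟩ and
⟨I⟩ the mean over the selected analysis window.  Spatial (RICS) estimator:
G(ξ, ψ) = ⟨δI(x, y) δI(x+ξ, y+ψ)⟩ₓᵧ / ⟨I⟩ₓᵧ², averaged over frames; the
scan timing maps each pixel lag to an effective lag time
τ(ξ, ψ) = ξ·t_pix + ψ·t_line.

Estimator conventions (documented because they matter at the 1e-3 level):
the temporal numerator uses the biased 1/M normalization (M = window
length) after FFT-based linear correlation with zero padding; the spatial
average ⟨·⟩ₓᵧ runs over the overlapping pixel pairs at each lag.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft

from .datatypes import Acf2D, AcfCurve, ImageStack, PhotonTrace, ScanGeometry, SectorGrid


# ---------------------------------------------------------------------------
# Temporal ACF (FCS)
# ---------------------------------------------------------------------------

def _autocorr_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased linear autocovariance of x for lags 0..n_lags-1 (1/M norm)."""
    m = x.size
    nfft = _fft.next_fast_len(m + n_lags)
    f = _fft.rfft(x, nfft)
    acov = _fft.irfft(f * np.conj(f), nfft)[:n_lags]
    return acov / m


def acf_fcs(trace: PhotonTrace, window: tuple = None,
            max_lag: float = None) -> AcfCurve:
    """Temporal ACF of a photon trace over an analysis window.

    Parameters
    ----------
    window:
        (t0, t1) in seconds relative to the trace start; None uses the full
        trace.  The mean used for δI and the normalization is the mean over
        this window.
    max_lag:
        Largest lag time (s); default min(0.1·window, 10⁵ bins).

    Returns dense linear lags bin_dt, 2·bin_dt, … up to max_lag.
    """
    dt = trace.bin_dt
    if window is None:
        i0, i1 = 0, trace.counts.size
    else:
        t0, t1 = window
        if not t0 < t1:
            raise ValueError("window must satisfy t0 < t1")
        i0 = max(0, int(round((t0 - trace.t_start) / dt)))
        i1 = min(trace.counts.size, int(round((t1 - trace.t_start) / dt)))
    x = np.asarray(trace.counts[i0:i1], dtype=float)
    if x.size < 2:
        raise ValueError("empty analysis window")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean intensity: normalization undefined")

    span = x.size * dt
    if max_lag is None:
        max_lag = min(0.1 * span, 1e5 * dt)
    if not 0 < max_lag < span:
        raise ValueError("max_lag must lie within the window span")
    n_lags = int(max_lag / dt)

    acov = _autocorr_fft(x - mean, n_lags + 1)
    g = acov[1:] / mean**2
    lags = dt * np.arange(1, n_lags + 1)
    return AcfCurve(lags=lags, g=g, n_traces=1,
                    attrs={**trace.attrs, "bin_dt": dt,
                           "window": (i0 * dt, i1 * dt)})


def acf_fcs_direct(trace: PhotonTrace, window: tuple = None,
                   max_lag: float = None) -> AcfCurve:
    """O(N·L) direct-sum temporal ACF (reference estimator for validation).

    Same definition and normalization as :func:`acf_fcs`.
    """
    dt = trace.bin_dt
    if window is None:
        x = np.asarray(trace.counts, dtype=float)
    else:
        t0, t1 = window
        i0 = max(0, int(round((t0 - trace.t_start) / dt)))
        i1 = min(trace.counts.size, int(round((t1 - trace.t_start) / dt)))
        x = np.asarray(trace.counts[i0:i1], dtype=float)
    mean = x.mean()
    span = x.size * dt
    if max_lag is None:
        max_lag = min(0.1 * span, 1e5 * dt)
    n_lags = int(max_lag / dt)
    d = x - mean
    g = np.array([np.sum(d[:x.size - k] * d[k:]) / x.size
                  for k in range(1, n_lags + 1)]) / mean**2
    return AcfCurve(lags=dt * np.arange(1, n_lags + 1), g=g, n_traces=1)


def mean_acf(curves: list) -> AcfCurve:
    """Average N ACF curves on an identical lag grid; sigma = SEM per lag."""
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    lags = curves[0].lags
    for c in curves[1:]:
        if c.lags.shape != lags.shape or not np.allclose(c.lags, lags):
            raise ValueError("curves must share one lag grid")
    gs = np.stack([c.g for c in curves])
    sigma = gs.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) >= 2 else None
    return AcfCurve(lags=lags, g=gs.mean(axis=0), sigma=sigma,
                    n_traces=len(curves), attrs=dict(curves[0].attrs))


# ---------------------------------------------------------------------------
# Spatial ACF (RICS)
# ---------------------------------------------------------------------------

def lag_time(xi, psi, geom: ScanGeometry):
    """Effective lag time of pixel displacement (ξ, ψ): ξ·t_pix + ψ·t_line."""
    return np.asarray(xi) * geom.t_pix + np.asarray(psi) * geom.t_line


def _frame_xcorr(a: np.ndarray, b: np.ndarray, xi_range, psi_range):
    """⟨a(x,y)·b(x+ξ,y+ψ)⟩ over overlapping pairs, via zero-padded FFT.

    a is the reference; positive ψ shifts toward increasing row index.
    """
    nr, nc = a.shape
    nfr = _fft.next_fast_len(2 * nr - 1)
    nfc = _fft.next_fast_len(2 * nc - 1)
    fa = _fft.rfft2(a, (nfr, nfc))
    fb = _fft.rfft2(b, (nfr, nfc))
    corr = _fft.irfft2(np.conj(fa) * fb, (nfr, nfc))
    # overlap count per lag
    ones = np.ones_like(a)
    f1 = _fft.rfft2(ones, (nfr, nfc))
    counts = _fft.irfft2(np.conj(f1) * f1, (nfr, nfc))
    out = np.empty((len(psi_range), len(xi_range)))
    for p, psi in enumerate(psi_range):
        for q, xi in enumerate(xi_range):
            out[p, q] = corr[psi % nfr, xi % nfc] / max(counts[psi % nfr, xi % nfc], 1.0)
    return out


def acf_rics(stack: ImageStack, background: np.ndarray = None,
             mode: str = "mean_normalize", xi_max: int = None,
             psi_max: int = None,
             normalization: str = "variance") -> Acf2D:
    """Spatial 2-D ACF of a raster image stack, averaged over frames.

    mode='mean_normalize' subtracts each frame's spatial mean and divides
    by the squared mean intensity (solution measurements, negligible
    background).  Note that per-frame mean subtraction constrains the
    summed correlation to zero, which depresses every lag by roughly
    Σ_lags G / n_pixels — negligible for weak correlations but visible in
    high-precision fits; for many-frame stacks the group-average
    background mode below avoids it.

    mode='background_subtract' subtracts a group-average image
    (``background``, e.g. ``stack.frames.mean(axis=0)`` or the average of
    an acquisition-condition slot) from each frame.  ``normalization``
    then selects the denominator: 'variance' (default; the variance of
    the background-subtracted signal, making G(0,0) ≈ 1),
    'variance_squared' (the literature's ambiguous "squared variance"
    read literally), or 'squared_mean' (squared mean of the background
    image, which keeps the 1/(V_eff⟨C⟩) amplitude semantics of the
    diffusion models and is the right choice when concentration is to be
    recovered).

    Per-point sigma is the SEM of per-frame ACF values (n_frames ≥ 2).
    """
    if stack.n_frames < 1:
        raise ValueError("empty stack")
    nr, nc = stack.frames.shape[1:]
    if mode not in ("mean_normalize", "background_subtract"):
        raise ValueError("unknown mode %r" % mode)
    if normalization not in ("variance", "variance_squared", "squared_mean"):
        raise ValueError("unknown normalization %r" % normalization)
    if mode == "background_subtract":
        if background is None:
            raise ValueError("background image required for background_subtract")
        background = np.asarray(background, dtype=float)
        if background.shape != (nr, nc):
            raise ValueError("background shape mismatch")
    if xi_max is None:
        xi_max = nc // 2
    if psi_max is None:
        psi_max = nr // 2
    xi_range = np.arange(-xi_max, xi_max + 1)
    psi_range = np.arange(0, psi_max + 1)

    per_frame = np.empty((stack.n_frames, psi_range.size, xi_range.size))
    for k in range(stack.n_frames):
        frame = np.asarray(stack.frames[k], dtype=float)
        if mode == "mean_normalize":
            mu = frame.mean()
            if mu == 0:
                raise ValueError("zero mean intensity in frame %d" % k)
            delta = frame - mu
            denom = mu**2
        else:
            delta = frame - background
            if normalization == "squared_mean":
                mu = background.mean()
                if mu == 0:
                    raise ValueError("zero mean background intensity")
                denom = mu**2
            else:
                var = delta.var()
                if var == 0:
                    raise ValueError("zero variance after background "
                                     "subtraction")
                denom = var**2 if normalization == "variance_squared" else var
        per_frame[k] = _frame_xcorr(delta, delta, xi_range, psi_range) / denom

    g = per_frame.mean(axis=0)
    sigma = (per_frame.std(axis=0, ddof=1) / np.sqrt(stack.n_frames)
             if stack.n_frames >= 2 else None)
    return Acf2D(g=g, xi_range=xi_range, psi_range=psi_range,
                 geometry=stack.geometry, sigma=sigma,
                 n_frames=stack.n_frames, attrs=dict(stack.attrs))


def acf_rics_direct(frame: np.ndarray, xi_range, psi_range) -> np.ndarray:
    """Brute-force double-sum spatial ACF of one frame (reference).

    Uses δI = I − ⟨I⟩ and the squared-mean normalization, averaging over
    overlapping pairs as in :func:`acf_rics` mean_normalize mode.
    """
    frame = np.asarray(frame, dtype=float)
    nr, nc = frame.shape
    mu = frame.mean()
    d = frame - mu
    out = np.empty((len(psi_range), len(xi_range)))
    for p, psi in enumerate(psi_range):
        for q, xi in enumerate(xi_range):
            acc, cnt = 0.0, 0
            for y in range(nr):
                for x in range(nc):
                    yy, xx = y + psi, x + xi
                    if 0 <= yy < nr and 0 <= xx < nc:
                        acc += d[y, x] * d[yy, xx]
                        cnt += 1
            out[p, q] = acc / cnt / mu**2
    return out


# ---------------------------------------------------------------------------
# Image splitting (sector grids)
# ---------------------------------------------------------------------------

def _even_centers(n: int, image_px: int, region_px: int) -> np.ndarray:
    """Evenly spaced integer centers so extreme regions touch the borders.

    A region of ``region_px`` at center c spans [c − region_px//2,
    c + region_px − region_px//2)."""
    lo = region_px // 2
    hi = image_px - (region_px - region_px // 2)
    if hi < lo:
        raise ValueError("correlation region larger than the image")
    if n == 1:
        centers = np.array([(lo + hi) / 2.0])
    else:
        centers = lo + np.arange(n) * (hi - lo) / (n - 1)
    # round ties toward the image center
    mid = image_px / 2.0
    out = np.where(centers <= mid, np.ceil(centers - 0.5),
                   np.floor(centers + 0.5))
    return out.astype(int)


def split_sectors(stack_shape: tuple, grid: SectorGrid, pixel_size: float):
    """Plan correlation regions for spatially resolved RICS.

    Returns a list of dicts with keys ``center`` (row, col pixels),
    ``region`` ((row0, row1), (col0, col1)) half-open pixel slices of the
    area to correlate, and ``reference`` (same structure, pair config only;
    None otherwise).
    """
    nr, nc = stack_shape
    sector_px = max(1, int(round(grid.sector_size / pixel_size)))
    if grid.config == "sector_self":
        corr_px = sector_px
    else:
        corr_px = max(1, int(round(grid.corr_size / pixel_size)))
        if corr_px < sector_px:
            raise ValueError("corr_size must not be smaller than sector_size")
    cx = _even_centers(grid.n_x, nc, corr_px)
    cy = _even_centers(grid.n_y, nr, corr_px)

    def _span(c, size):
        lo = c - size // 2
        return (int(lo), int(lo + size))

    regions = []
    for y in cy:
        for x in cx:
            r = {"center": (int(y), int(x)),
                 "region": (_span(y, corr_px), _span(x, corr_px)),
                 "reference": None}
            if grid.config == "pair":
                r["reference"] = (_span(y, sector_px), _span(x, sector_px))
            (r0, r1), (c0, c1) = r["region"]
            if r0 < 0 or c0 < 0 or r1 > nr or c1 > nc:
                raise ValueError("correlation region exits the image")
            regions.append(r)
    return regions


# ---------------------------------------------------------------------------
# Cropping and logarithmic downsampling
# ---------------------------------------------------------------------------

def _log_bin(lags, g, sigma, n_bins):
    """Average (lags, g) within logarithmically spaced lag bins.

    Besides the bin-mean lags and values, returns per-bin representative
    source lags (up to 7 per bin, evenly subsampled) so that model curves
    can be averaged over the same bins during fitting — comparing a
    bin-mean of a convex ACF against the model at the mean lag alone would
    bias fast-timescale parameters.
    """
    edges = np.geomspace(lags[0], lags[-1], n_bins + 1)
    edges[-1] *= 1.0 + 1e-12
    idx = np.searchsorted(edges, lags, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    out_l, out_g, out_s, reps = [], [], [], []
    for b in range(n_bins):
        m = idx == b
        cnt = int(m.sum())
        if cnt == 0:
            continue
        out_l.append(lags[m].mean())
        out_g.append(g[m].mean())
        sub = lags[m]
        if cnt > 7:
            sub = sub[np.linspace(0, cnt - 1, 7).round().astype(int)]
        reps.append([float(v) for v in sub])
        if sigma is not None:
            out_s.append(np.sqrt(np.sum(sigma[m] ** 2)) / cnt)
    return (np.array(out_l), np.array(out_g),
            np.array(out_s) if sigma is not None else None, reps)


def crop_and_downsample(acf, drop_first: int = 0, n_lines: int = 3,
                        points_per_line: int = None, log_bins: int = None):
    """Restrict an ACF to the portion used for fitting.

    For an :class:`AcfCurve`: drop the first ``drop_first`` lags (detector
    shot noise / fast photophysics), optionally average into ``log_bins``
    logarithmic lag bins (sigma propagated as SEM of the bin mean).

    For an :class:`Acf2D`: keep the positive-lag quadrant, the first
    ``n_lines`` ψ-lines, drop ``drop_first`` ξ-points per line, and cap
    ``points_per_line``.
    """
    if isinstance(acf, AcfCurve):
        lags, g = acf.lags[drop_first:], acf.g[drop_first:]
        sigma = acf.sigma[drop_first:] if acf.sigma is not None else None
        if points_per_line is not None:
            lags, g = lags[:points_per_line], g[:points_per_line]
            sigma = sigma[:points_per_line] if sigma is not None else None
        if lags.size == 0:
            raise ValueError("nothing left after cropping")
        attrs = dict(acf.attrs)
        if log_bins is not None:
            lags, g, sigma, reps = _log_bin(lags, g, sigma, log_bins)
            attrs["bin_rep_lags"] = reps
        return AcfCurve(lags=lags, g=g, sigma=sigma, n_traces=acf.n_traces,
                        attrs=attrs)

    if isinstance(acf, Acf2D):
        pidx = np.where(acf.psi_range >= 0)[0][:n_lines]
        xidx = np.where(acf.xi_range >= drop_first)[0]
        if points_per_line is not None:
            xidx = xidx[:points_per_line]
        if xidx.size == 0 or pidx.size == 0:
            raise ValueError("nothing left after cropping")
        g = acf.g[np.ix_(pidx, xidx)]
        sigma = acf.sigma[np.ix_(pidx, xidx)] if acf.sigma is not None else None
        return Acf2D(g=g, xi_range=acf.xi_range[xidx],
                     psi_range=acf.psi_range[pidx], geometry=acf.geometry,
                     sigma=sigma, n_frames=acf.n_frames, attrs=dict(acf.attrs))
    raise TypeError("expected AcfCurve or Acf2D")
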