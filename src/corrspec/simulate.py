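"""Brownian-dynamics fluorescence-fluctuation simulator.

Free Brownian diffusion of point emitters in a periodic box, PSF-weighted
Poisson photon emission.  Point (FCS) traces sample the emission at a fixed
focus at the box center; raster (RICS) stacks sample it along the scan
trajectory, with particles diffusing continuously through pixel dwells and
line flyback.

The default configuration reproduces standard synthetic single-trace
conditions: 100 particles in a 2.5 × 2.5 × 7 μm³ box, DC = 100 μm²/s,
80 s at dt = 1 μs, Gaussian PSF with ω_xy = 0.3 μm, ω_z = 1.1 μm.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import GaussianPsf, ImageStack, PhotonTrace, SimConfig

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

DEFAULT_PSF = GaussianPsf(0.3, 0.3, 1.1)

# time-chunk length for the FCS particle loop; bounds peak memory at
# ~5 arrays × chunk doubles per particle
_CHUNK = 2_000_000


def _psf_weights(psf: GaussianPsf, d: np.ndarray) -> np.ndarray:
    """Peak-normalized Gaussian PSF evaluated at displacements d (..., 3)."""
    w = psf.waists
    q = (d / w) ** 2
    return np.exp(-2.0 * q.sum(axis=-1))


def _check_box(cfg: SimConfig, psf: GaussianPsf) -> None:
    w = psf.waists
    if np.any(np.asarray(cfg.box) < 5.0 * w):
        warnings.warn(
            "box smaller than 5x the PSF waist on some axis; periodic images "
            "of the focal volume may overlap", stacklevel=3)


if _HAVE_NUMBA:
    @_njit(cache=False)
    def _accumulate(intensity, i0, steps, x, y, z, bx, by, bz,
                    fx, fy, fz, iwx, iwy, iwz):
        """Integrate one particle through a chunk of Brownian steps,
        adding its PSF weight at each bin start; periodic wrap."""
        m = steps.shape[0]
        for j in range(m):
            dx = (x - fx) * iwx
            dy = (y - fy) * iwy
            dz = (z - fz) * iwz
            q = dx * dx + dy * dy + dz * dz
            # exp(-2q) < 4e-9 beyond q = 10: negligible against shot noise
            if q < 10.0:
                intensity[i0 + j] += np.exp(-2.0 * q)
            x += steps[j, 0]
            while x < 0.0:
                x += bx
            while x >= bx:
                x -= bx
            y += steps[j, 1]
            while y < 0.0:
                y += by
            while y >= by:
                y -= by
            z += steps[j, 2]
            while z < 0.0:
                z += bz
            while z >= bz:
                z -= bz
        return x, y, z


def simulate_fcs_trace(cfg: SimConfig, return_trajectories: bool = False,
                       traj_stride: int = 1000):
    """Simulate a point-FCS photon trace.

    Each particle takes independent Gaussian steps of per-axis std
    sqrt(2·DCi·dt) with periodic wrap; the expected count in each bin is
    dt·(background + brightness·Σ_k PSF(r_k − r_focus)), and counts are
    Poisson draws.  Reproducible given ``cfg.seed``.

    Parameters
    ----------
    return_trajectories:
        Also return unwrapped particle positions subsampled every
        ``traj_stride`` steps (for transport diagnostics such as MSD).
    """
    if cfg.scan is not None:
        raise ValueError("cfg.scan must be absent for point FCS")
    psf = cfg.psf if cfg.psf is not None else DEFAULT_PSF
    _check_box(cfg, psf)

    n_bins = int(round(cfg.duration / cfg.dt))
    if n_bins < 1 or n_bins > 2**31:
        raise ValueError("duration/dt gives an unusable trace length")
    box = np.asarray(cfg.box, dtype=float)
    focus = box / 2.0
    sig = np.sqrt(2.0 * np.asarray(cfg.dc_true, dtype=float) * cfg.dt)

    rng = np.random.default_rng(cfg.seed)
    x0 = rng.uniform(0.0, box, size=(cfg.n_particles, 3))
    inv_w = 1.0 / psf.waists

    use_kernel = _HAVE_NUMBA and not return_trajectories
    intensity = np.zeros(n_bins)
    trajs = [] if return_trajectories else None
    for k in range(cfg.n_particles):
        pos = x0[k].copy()          # unwrapped (numpy path) / wrapped (kernel)
        ptraj = [] if return_trajectories else None
        for start in range(0, n_bins, _CHUNK):
            m = min(_CHUNK, n_bins - start)
            # steps[j] moves the particle from bin start j to j+1
            steps = rng.standard_normal((m, 3)) * sig
            if use_kernel:
                pos[:] = _accumulate(
                    intensity, start, steps, pos[0], pos[1], pos[2],
                    box[0], box[1], box[2], focus[0], focus[1], focus[2],
                    inv_w[0], inv_w[1], inv_w[2])
            else:
                # positions at bin starts: cumulative steps, excluding the
                # bin's own step
                path = pos + np.cumsum(steps, axis=0) - steps
                wrapped = np.mod(path, box)
                intensity[start:start + m] += _psf_weights(psf,
                                                           wrapped - focus)
                if return_trajectories:
                    ptraj.append(path[::traj_stride].copy())
                pos = path[-1] + steps[-1]
        if return_trajectories:
            trajs.append(np.concatenate(ptraj, axis=0))

    mean_counts = cfg.dt * (cfg.background + cfg.brightness * intensity)
    counts = rng.poisson(mean_counts)
    trace = PhotonTrace(
        counts=counts.astype(np.int64), bin_dt=cfg.dt,
        attrs={
            "ground_truth": {
                "dc": tuple(cfg.dc_true), "n_particles": cfg.n_particles,
                "box": tuple(cfg.box), "brightness": cfg.brightness,
                "background": cfg.background, "seed": cfg.seed,
                "concentration": cfg.concentration,
                "psf_waists": tuple(psf.waists),
            },
        },
    )
    if return_trajectories:
        return trace, np.stack(trajs), cfg.dt * traj_stride
    return trace


def _scan_sample_times_and_focus(geom, n_frames: int, box: np.ndarray):
    """Absolute sample times and sample-frame focus positions, raster order.

    Pixel (frame k, row j, col i) is sampled at
    t = k·n_rows·t_line + j·t_line + i·t_pix; the focus is displaced from the
    box center by the z-rotation (scan angle α) of the pixel-space offset.
    """
    nr, nc = geom.n_rows, geom.n_cols
    i = np.arange(nc)
    j = np.arange(nr)
    k = np.arange(n_frames)
    t = (k[:, None, None] * geom.frame_time
         + j[None, :, None] * geom.t_line
         + i[None, None, :] * geom.t_pix).ravel()

    u = (i - (nc - 1) / 2.0) * geom.s_xi      # fast-scan offset
    v = (j - (nr - 1) / 2.0) * geom.s_psi     # slow-scan offset
    uu, vv = np.meshgrid(u, v)                # (nr, nc)
    a = np.deg2rad(geom.alpha)
    fx = np.cos(a) * uu - np.sin(a) * vv
    fy = np.sin(a) * uu + np.cos(a) * vv
    focus = np.empty((nr * nc, 3))
    focus[:, 0] = fx.ravel() + box[0] / 2.0
    focus[:, 1] = fy.ravel() + box[1] / 2.0
    focus[:, 2] = box[2] / 2.0
    focus = np.tile(focus, (n_frames, 1))
    return t, focus


def simulate_rics_stack(cfg: SimConfig, n_frames: int) -> ImageStack:
    """Simulate a raster-scanned image stack.

    Particles diffuse continuously in real time (including through flyback,
    when no photons are recorded); each pixel integrates the emission over
    its dwell time t_pix, approximated by the instantaneous intensity at the
    pixel sample time.
    """
    if cfg.scan is None:
        raise ValueError("cfg.scan required for a raster simulation")
    geom = cfg.scan
    if geom.n_cols < 1 or geom.n_rows < 1:
        raise ValueError("scan geometry needs n_cols and n_rows")
    psf = cfg.psf if cfg.psf is not None else DEFAULT_PSF
    _check_box(cfg, psf)
    box = np.asarray(cfg.box, dtype=float)
    img_w = geom.n_cols * geom.s_xi
    img_h = geom.n_rows * geom.s_psi
    if img_w > box[0] or img_h > box[1]:
        raise ValueError("scanned area does not fit inside the box")

    t, focus = _scan_sample_times_and_focus(geom, n_frames, box)
    dts = np.diff(t, prepend=0.0)
    sig = np.sqrt(2.0 * np.asarray(cfg.dc_true) * dts[:, None])  # (n, 3)

    rng = np.random.default_rng(cfg.seed)
    x0 = rng.uniform(0.0, box, size=(cfg.n_particles, 3))
    intensity = np.zeros(t.size)
    for k in range(cfg.n_particles):
        path = x0[k] + np.cumsum(rng.standard_normal((t.size, 3)) * sig,
                                 axis=0)
        d = np.mod(path, box) - focus
        # minimum-image displacement to the focus
        d -= box * np.round(d / box)
        intensity += _psf_weights(psf, d)

    mean_counts = geom.t_pix * (cfg.background + cfg.brightness * intensity)
    counts = rng.poisson(mean_counts).astype(np.int64)
    frames = counts.reshape(n_frames, geom.n_rows, geom.n_cols)
    return ImageStack(
        frames=frames, geometry=geom,
        attrs={
            "ground_truth": {
                "dc": tuple(cfg.dc_true), "n_particles": cfg.n_particles,
                "box": tuple(cfg.box), "brightness": cfg.brightness,
                "background": cfg.background, "seed": cfg.seed,
                "concentration": cfg.concentration,
                "psf_waists": tuple(psf.waists),
            },
            "angle": geom.alpha,
        },
    )
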