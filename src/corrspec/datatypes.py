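"""Shared domain containers for FCS/RICS correlation spectroscopy.

Units convention throughout the package: time in seconds, lengths in μm,
diffusion coefficients in μm²/s, concentrations internally in molecules/μm³
(user-facing I/O in nM; 1 nM = 0.6022 molecules/μm³), photon rates in
counts/s.  PSF waists are 1/e² radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: molecules per μm³ for a 1 nM solution (Avogadro constant × 1 nM)
NM_TO_MOLEC_PER_UM3 = 0.6022


def nm_to_molecules(c_nm: float) -> float:
    """Concentration nM → molecules/μm³."""
    return c_nm * NM_TO_MOLEC_PER_UM3


def molecules_to_nm(c: float) -> float:
    """Concentration molecules/μm³ → nM."""
    return c / NM_TO_MOLEC_PER_UM3


# ---------------------------------------------------------------------------
# Raw data containers
# ---------------------------------------------------------------------------

@dataclass
class PhotonTrace:
    """Binned photon counts from a point (FCS) measurement.

    ``counts[i]`` is the number of photons detected in the time bin
    ``[t_start + i*bin_dt, t_start + (i+1)*bin_dt)``.
    """

    counts: np.ndarray
    bin_dt: float
    t_start: float = 0.0
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("counts must be a 1-D array of length >= 2")
        if not self.bin_dt > 0:
            raise ValueError("bin_dt must be positive")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_dt

    @property
    def times(self) -> np.ndarray:
        """Bin start times."""
        return self.t_start + np.arange(self.counts.size) * self.bin_dt


@dataclass
class ScanGeometry:
    """Raster-scan timing and pixel geometry.

    ``t_line`` includes the flyback dead time, so ``t_line >= n_cols*t_pix``.
    ``alpha`` is the scan angle in degrees: pixel-space displacements
    (ξ, ψ, ζ) map to sample-frame displacements through a rotation about z
    by ``alpha``.
    """

    t_pix: float
    t_line: float
    s_xi: float
    s_psi: float
    s_zeta: float = 0.0
    alpha: float = 0.0
    n_cols: int = 0
    n_rows: int = 0

    def __post_init__(self) -> None:
        if self.t_pix <= 0 or self.t_line <= 0:
            raise ValueError("t_pix and t_line must be positive")
        if self.s_xi <= 0 or self.s_psi <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.n_cols and self.t_line < self.n_cols * self.t_pix - 1e-15:
            raise ValueError(
                "t_line (%g s) smaller than n_cols*t_pix (%g s): negative flyback"
                % (self.t_line, self.n_cols * self.t_pix)
            )

    @property
    def flyback(self) -> float:
        """Dead time at the end of each line (s)."""
        return self.t_line - self.n_cols * self.t_pix

    @property
    def frame_time(self) -> float:
        return self.n_rows * self.t_line


@dataclass
class ImageStack:
    """RICS image stack: ``frames`` has shape (n_frames, n_rows, n_cols)."""

    frames: np.ndarray
    geometry: ScanGeometry
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (n_frames, n_rows, n_cols)")
        if np.any(self.frames < 0):
            raise ValueError("counts must be non-negative")
        nf, nr, nc = self.frames.shape
        if self.geometry.n_cols and self.geometry.n_cols != nc:
            raise ValueError("geometry.n_cols inconsistent with frame shape")
        if self.geometry.n_rows and self.geometry.n_rows != nr:
            raise ValueError("geometry.n_rows inconsistent with frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Correlation containers
# ---------------------------------------------------------------------------

@dataclass
class AcfCurve:
    """Temporal autocorrelation G(τ) with optional per-lag SEM."""

    lags: np.ndarray
    g: np.ndarray
    sigma: Optional[np.ndarray] = None
    n_traces: int = 1
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.shape != self.g.shape:
            raise ValueError("lags and g must have identical shapes")
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.g.shape:
                raise ValueError("sigma must match g in shape")
            if np.any(self.sigma < 0):
                raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return self.g.size


@dataclass
class Acf2D:
    """Spatial autocorrelation G(ξ, ψ) of a raster image stack.

    ``g[p, x]`` is the correlation at line lag ``psi_range[p]`` and pixel lag
    ``xi_range[x]``; element at (ψ=0, ξ=0) is the zero-lag value.
    """

    g: np.ndarray
    xi_range: np.ndarray
    psi_range: np.ndarray
    geometry: ScanGeometry
    sigma: Optional[np.ndarray] = None
    n_frames: int = 1
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.xi_range = np.asarray(self.xi_range, dtype=int)
        self.psi_range = np.asarray(self.psi_range, dtype=int)
        if self.g.shape != (self.psi_range.size, self.xi_range.size):
            raise ValueError("g shape must be (len(psi_range), len(xi_range))")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.g.shape:
                raise ValueError("sigma must match g in shape")


@dataclass
class SectorGrid:
    """Image-splitting specification for spatially resolved correlation.

    config:
      ``sector_self``  — each sector correlated with itself;
      ``larger_self``  — a larger concentric area (corr_size) correlated
                         with itself;
      ``pair``         — sector-sized reference area cross-correlated with a
                         concentric larger (corr_size) area.
    Sizes in μm (converted to pixels with the stack's pixel sizes).
    """

    config: str
    n_x: int
    n_y: int
    sector_size: float
    corr_size: Optional[float] = None

    def __post_init__(self) -> None:
        if self.config not in ("sector_self", "larger_self", "pair"):
            raise ValueError("config must be sector_self, larger_self or pair")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("sector counts must be >= 1")
        if self.sector_size <= 0:
            raise ValueError("sector_size must be positive")
        if self.config in ("larger_self", "pair") and not self.corr_size:
            raise ValueError("corr_size required for larger_self/pair")


# ---------------------------------------------------------------------------
# PSF containers
# ---------------------------------------------------------------------------

@dataclass
class GaussianPsf:
    """3-D Gaussian-ellipsoid PSF, exp(−2x²/ωx² − 2y²/ωy² − 2z²/ωz²).

    Waists are 1/e² radii in μm.  ``scale`` multiplies all three waists
    (a fit parameter constrained to [0, 2])."""

    w_x: float
    w_y: float
    w_z: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_x, self.w_y, self.w_z) <= 0:
            raise ValueError("waists must be positive")
        if not 0 <= self.scale <= 2:
            raise ValueError("scale must lie in [0, 2]")

    @property
    def waists(self) -> np.ndarray:
        """Effective (scaled) waists."""
        return self.scale * np.array([self.w_x, self.w_y, self.w_z])


@dataclass
class PsfGrid:
    """Measured PSF sampled on a voxel grid, peak-normalized on storage.

    ``values[ix, iy, iz]``; ``voxel`` gives (vx, vy, vz) in μm.  The grid
    center (``(shape-1)/2`` voxel) is the nominal PSF center after centroid
    alignment."""

    values: np.ndarray
    voxel: tuple
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("PSF grid must be 3-D")
        if np.any(self.values < 0):
            raise ValueError("PSF values must be non-negative")
        peak = self.values.max()
        if peak <= 0:
            raise ValueError("PSF grid must not be all-zero")
        self.values = self.values / peak
        self.voxel = tuple(float(v) for v in self.voxel)
        if len(self.voxel) != 3 or min(self.voxel) <= 0:
            raise ValueError("voxel must be three positive sizes")

    @property
    def voxel_volume(self) -> float:
        vx, vy, vz = self.voxel
        return vx * vy * vz


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Brownian-dynamics fluorescence-fluctuation simulation settings.

    ``brightness`` is counts/s per molecule at the PSF peak; the expected
    count in a bin of width dt is
    ``dt * (background + brightness * Σ_k PSF(r_k − r_focus))`` with the PSF
    peak-normalized.  ``scan is None`` means point FCS at the box center.
    """

    n_particles: int = 100
    box: tuple = (2.5, 2.5, 7.0)
    dc_true: tuple = (100.0, 100.0, 100.0)
    duration: float = 80.0
    dt: float = 1e-6
    brightness: float = 30000.0
    background: float = 0.0
    psf: object = None  # GaussianPsf (default set in simulate)
    seed: int = 0
    scan: Optional[ScanGeometry] = None

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if min(self.box) <= 0:
            raise ValueError("box lengths must be positive")
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if min(self.dc_true) < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        for v in (*self.box, *self.dc_true, self.duration, self.dt,
                  self.brightness, self.background):
            if not np.isfinite(v):
                raise ValueError("non-finite simulation parameter")

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def concentration(self) -> float:
        """Mean concentration, molecules/μm³."""
        return self.n_particles / self.box_volume


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass
class DiffusionParams:
    """Parameters of the diffusion + triplet correlation models.

    kind ∈ {iso1, aniso1, iso2, aniso2}; for iso kinds all axes share one
    DC.  ``c_mean`` is in molecules/μm³.  ``tsa``/``tau_t`` give the
    triplet (dark-state) blinking factor; tsa=0 disables it.
    """

    kind: str = "iso1"
    dc: tuple = (1.0, 1.0, 1.0)
    dc2: Optional[tuple] = None
    f: float = 1.0
    c_mean: float = 1.0
    tsa: float = 0.0
    tau_t: float = 1e-5

    def __post_init__(self) -> None:
        if self.kind not in ("iso1", "aniso1", "iso2", "aniso2"):
            raise ValueError("unknown model kind %r" % self.kind)
        self.dc = tuple(float(d) for d in np.broadcast_to(self.dc, (3,)))
        if min(self.dc) < 0:
            raise ValueError("DCs must be >= 0")
        if self.kind in ("iso2", "aniso2"):
            if self.dc2 is None:
                raise ValueError("two-component kind requires dc2")
            self.dc2 = tuple(float(d) for d in np.broadcast_to(self.dc2, (3,)))
            if min(self.dc2) < 0:
                raise ValueError("DCs must be >= 0")
        if not 0 <= self.f <= 1:
            raise ValueError("fraction f must lie in [0, 1]")
        if self.c_mean <= 0:
            raise ValueError("mean concentration must be positive")
        if not 0 <= self.tsa < 1:
            raise ValueError("TSA must lie in [0, 1)")
        if self.tsa > 0 and self.tau_t <= 0:
            raise ValueError("tau_t must be positive when TSA > 0")


@dataclass
class ModelSpec:
    """Which forward model to fit.

    ``aniso_mode`` applies to aniso kinds: 'full' fits DCx, DCy, DCz
    independently, 'uniaxial' ties DCy = DCz, 'quasi2d' fixes DCz = 0.
    """

    kind: str = "iso1"
    triplet: bool = False
    aniso_mode: str = "uniaxial"
    fit_scale: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("iso1", "aniso1", "iso2", "aniso2"):
            raise ValueError("unknown model kind %r" % self.kind)
        if self.aniso_mode not in ("full", "uniaxial", "quasi2d"):
            raise ValueError("unknown aniso_mode %r" % self.aniso_mode)


# ---------------------------------------------------------------------------
# Inference containers
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """OLS (uniform), WLS (per-point σ) or GLS (full covariance Σ) errors."""

    mode: str = "OLS"
    sigma: Optional[np.ndarray] = None
    cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode not in ("OLS", "WLS", "GLS"):
            raise ValueError("mode must be OLS, WLS or GLS")
        if self.mode == "WLS":
            if self.sigma is None:
                raise ValueError("WLS requires per-point sigma")
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("WLS sigma must be positive")
        if self.mode == "GLS":
            if self.cov is None:
                raise ValueError("GLS requires a covariance matrix")
            self.cov = np.asarray(self.cov, dtype=float)
            if self.cov.ndim != 2 or self.cov.shape[0] != self.cov.shape[1]:
                raise ValueError("covariance must be square")


@dataclass
class PriorSpec:
    """Per-parameter uniform prior bounds (lower, upper).

    Defaults: DC 0–5000 μm²/s, C 0–1000 nM, TSA 0–1, τ_T 0.01–10⁴ μs,
    PSF scale 0–2, component fraction f 0–1.
    """

    bounds: dict = field(default_factory=dict)

    DEFAULTS = {
        "dc": (0.0, 5000.0),
        "c": (0.0, 1000.0),        # nM
        "tsa": (0.0, 1.0),
        "tau_t": (1e-8, 1e-2),     # s (0.01–1e4 μs)
        "scale": (0.0, 2.0),
        "f": (0.0, 1.0),
    }

    def get(self, name: str) -> tuple:
        if name in self.bounds:
            lo, hi = self.bounds[name]
        else:
            if name.startswith("dc") or name.startswith("ddc"):
                base = "dc"
            elif name == "c":
                base = "c"
            else:
                base = name
            lo, hi = self.DEFAULTS.get(base, (0.0, 1.0))
        if not lo < hi:
            raise ValueError("prior lower bound must be below upper bound")
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("prior bounds must be finite")
        return float(lo), float(hi)


@dataclass
class FitResult:
    """Point-estimate fit with χ² metrics and residual transforms."""

    param_names: list
    theta: np.ndarray
    stderr: np.ndarray
    ssr: float
    chi2: float
    chi2_red: float
    n: int
    p: int
    residuals: np.ndarray
    residuals_transformed: np.ndarray
    converged: bool
    error_mode: str = "OLS"
    attrs: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return float(self.theta[self.param_names.index(name)])

    def stderr_of(self, name: str) -> float:
        return float(self.stderr[self.param_names.index(name)])


@dataclass
class PosteriorResult:
    """Weighted posterior samples with evidence from nested sampling."""

    param_names: list
    samples: np.ndarray          # (n_samples, n_params), equal-weight
    log_z: float
    log_z_err: float
    n_data: int = 0
    error_mode: str = "OLS"
    attrs: dict = field(default_factory=dict)

    def _col(self, name: str) -> np.ndarray:
        return self.samples[:, self.param_names.index(name)]

    def mean(self, name: str) -> float:
        return float(np.mean(self._col(name)))

    def median(self, name: str) -> float:
        return float(np.median(self._col(name)))

    def std(self, name: str) -> float:
        return float(np.std(self._col(name)))

    def quantile_range(self, name: str, level: float = 0.683) -> tuple:
        """Central credible interval at the given level (0.683 or 0.955)."""
        q = (1.0 - level) / 2.0
        col = self._col(name)
        return (float(np.quantile(col, q)), float(np.quantile(col, 1 - q)))

    @property
    def median_theta(self) -> np.ndarray:
        return np.median(self.samples, axis=0)


@dataclass
class ParameterMap:
    """Spatial map of one fitted parameter over a sector grid."""

    name: str
    units: str
    grid: np.ndarray             # (n_y, n_x); NaN where masked
    mask: np.ndarray             # True where the sector fit failed/excluded
    centers_x: np.ndarray        # μm from image origin
    centers_y: np.ndarray
    attrs: dict = field(default_factory=dict)

    @property
    def masked_fraction(self) -> float:
        return float(np.mean(self.mask))
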