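"""Spatial parameter maps from sector-wise RICS fits and angular summaries.

Each sector of an image-splitting grid gets its own spatial ACF and model
fit; the fitted DC (μm²/s) and C (nM) become map cells.  Failed sectors
are masked with a recorded reason — maps never interpolate over failures.
Map orientation: row 0 is the top of the image; centers are in μm from the
image origin.
"""

from __future__ import annotations

import numpy as np

from .correlate import acf_rics, crop_and_downsample, split_sectors
from .datatypes import (Acf2D, ErrorModel, ImageStack, ModelSpec,
                        ParameterMap, PriorSpec, SectorGrid)
from .inference import fit_nls

_UNITS = {"dc": "um^2/s", "dc_x": "um^2/s", "dc_y": "um^2/s",
          "dc_z": "um^2/s", "dc_yz": "um^2/s", "c": "nM", "tsa": "",
          "tau_t": "s", "f": "", "scale": ""}


def sector_acf(stack: ImageStack, region, reference=None,
               mode: str = "mean_normalize", background=None,
               **acf_kw) -> Acf2D:
    """Spatial ACF of one sector region of the stack."""
    (r0, r1), (c0, c1) = region
    sub = ImageStack(frames=stack.frames[:, r0:r1, c0:c1],
                     geometry=_subgeometry(stack.geometry, c1 - c0, r1 - r0),
                     attrs=dict(stack.attrs))
    bg = background[r0:r1, c0:c1] if background is not None else None
    return acf_rics(sub, background=bg, mode=mode, **acf_kw)


def _subgeometry(geom, n_cols, n_rows):
    from dataclasses import replace
    return replace(geom, n_cols=n_cols, n_rows=n_rows)


def map_parameters(stack: ImageStack, grid: SectorGrid, spec: ModelSpec,
                   psf, em: ErrorModel = None, priors: PriorSpec = None,
                   mode: str = "mean_normalize", background=None,
                   drop_first: int = 0, n_lines: int = 3,
                   points_per_line: int = None):
    """Fit every sector and return one :class:`ParameterMap` per parameter.

    The per-sector error model defaults to OLS; WLS uses the per-point SEM
    across frames (requires ≥ 2 frames).  GLS is not available for raster
    data.
    """
    em = em or ErrorModel(mode="OLS")
    if em.mode == "GLS":
        raise ValueError("GLS is not supported for raster sector fits")
    regions = split_sectors(stack.frames.shape[1:], grid,
                            pixel_size=stack.geometry.s_xi)
    n_y, n_x = grid.n_y, grid.n_x
    maps = {}
    mask = np.zeros((n_y, n_x), dtype=bool)
    reasons = {}
    names = None
    for idx, reg in enumerate(regions):
        iy, ix = divmod(idx, n_x)
        try:
            acf = sector_acf(stack, reg["region"], mode=mode,
                             background=background)
            acf = crop_and_downsample(acf, drop_first=drop_first,
                                      n_lines=n_lines,
                                      points_per_line=points_per_line)
            local_em = em
            if em.mode == "WLS":
                if acf.sigma is None:
                    raise ValueError("WLS needs >= 2 frames for per-point SEM")
                local_em = ErrorModel(mode="WLS",
                                      sigma=np.clip(acf.sigma.ravel(),
                                                    1e-30, None))
            fit = fit_nls(acf, spec, psf, local_em, priors)
            names = fit.param_names
            for nm, val in zip(fit.param_names, fit.theta):
                maps.setdefault(nm, np.full((n_y, n_x), np.nan))[iy, ix] = val
        except Exception as exc:
            mask[iy, ix] = True
            reasons[(iy, ix)] = str(exc)
    if names is None:
        raise RuntimeError("every sector fit failed; first reason: %s"
                           % next(iter(reasons.values()), "no sectors"))

    centers_x = np.array(sorted({r["center"][1] for r in regions}),
                         dtype=float) * stack.geometry.s_xi
    centers_y = np.array(sorted({r["center"][0] for r in regions}),
                         dtype=float) * stack.geometry.s_psi
    out = []
    for nm in names:
        gridvals = maps[nm]
        gridvals[mask] = np.nan
        out.append(ParameterMap(
            name=nm, units=_UNITS.get(nm, ""), grid=gridvals, mask=mask,
            centers_x=centers_x, centers_y=centers_y,
            attrs={"masked_fraction": float(mask.mean()),
                   "fail_reasons": {str(k): v for k, v in reasons.items()}}))
    return out


def angular_summary(fits_by_angle: dict, flag_sigma: float = 2.0):
    """Tabulate per-angle DC estimates; flag anisotropy in joint fits.

    ``fits_by_angle`` maps angle (degrees) to a FitResult or
    PosteriorResult.  For anisotropic fits the DCx/DCy(z) difference is
    flagged when it exceeds ``flag_sigma`` × the combined uncertainty.
    Returns (rows, anisotropy_flag).
    """
    if len(fits_by_angle) < 2:
        raise ValueError("need fits at >= 2 angles")
    rows = []
    flag = False
    for angle in sorted(fits_by_angle):
        fit = fits_by_angle[angle]
        row = {"angle": float(angle)}
        names = fit.param_names
        for nm in names:
            if nm.startswith("dc"):
                if hasattr(fit, "stderr"):
                    row[nm] = fit[nm]
                    row[nm + "_err"] = fit.stderr_of(nm)
                else:
                    row[nm] = fit.mean(nm)
                    row[nm + "_err"] = fit.std(nm)
        dcx, dcy = row.get("dc_x"), row.get("dc_y", row.get("dc_yz"))
        if dcx is not None and dcy is not None:
            ex = row.get("dc_x_err", 0.0)
            ey = row.get("dc_y_err", row.get("dc_yz_err", 0.0))
            comb = float(np.hypot(ex, ey))
            row["anisotropic"] = bool(abs(dcx - dcy) > flag_sigma * comb > 0)
            flag = flag or row["anisotropic"]
        rows.append(row)
    return rows, flag
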