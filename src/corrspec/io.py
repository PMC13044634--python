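"""HDF5 persistence for traces, stacks, ACFs, PSFs and fit results, plus
NetCDF posterior export and TIFF bead-stack reading.

Layout (one file can hold everything; names chosen by the caller):

    /traces/<name>        counts;      attrs: bin_dt, t_start, units, ...
    /images/<name>        frames;      attrs: t_pix, t_line, s_xi, s_psi,
                                       s_zeta, alpha, n_cols, n_rows, ...
    /acf/<name>           g, lags[, sigma];           attrs: n_traces, ...
    /acf2d/<name>         g, xi_range, psi_range[, sigma]; scan attrs
    /psf/<name>           values;      attrs: voxel
    /fits/<name>          theta, stderr, residuals, residuals_transformed;
                          attrs: param_names, ssr, chi2, chi2_red, n, p, ...
    /ground_truth         attribute group written by the simulator

Every group carries ``schema_version`` and ``software`` attributes; arrays
are stored at full (float64/int64) precision.  Posteriors go to NetCDF
(classic format, written through xarray) with variables prefixed
``posterior_`` and ``sample_stats_`` and the log-evidence as global
attributes.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .datatypes import (Acf2D, AcfCurve, FitResult, ImageStack, PhotonTrace,
                        PosteriorResult, PsfGrid, ScanGeometry)

SCHEMA_VERSION = 1
_SOFTWARE = "corrspec"


def _stamp(group, extra_attrs: dict) -> None:
    group.attrs["schema_version"] = SCHEMA_VERSION
    group.attrs["software"] = _SOFTWARE
    for key, val in extra_attrs.items():
        if isinstance(val, (dict, list, tuple)) and key == "ground_truth":
            group.attrs[key] = json.dumps(val)
        elif isinstance(val, dict):
            group.attrs[key] = json.dumps(val)
        elif val is None:
            continue
        else:
            try:
                group.attrs[key] = val
            except (TypeError, ValueError):
                # ragged lists and other non-rectangular values go as JSON
                group.attrs[key] = json.dumps(val)


def _check_version(group) -> None:
    ver = group.attrs.get("schema_version")
    if ver is None:
        raise ValueError("missing schema_version attribute: unknown layout")
    if int(ver) != SCHEMA_VERSION:
        raise ValueError("unsupported schema version %r" % ver)


def _load_attrs(group, skip=()) -> dict:
    out = {}
    for key, val in group.attrs.items():
        if key in ("schema_version", "software") or key in skip:
            continue
        if isinstance(val, bytes):
            val = val.decode()
        if isinstance(val, str) and val[:1] in "[{":
            try:
                val = json.loads(val)
            except ValueError:
                pass
        if isinstance(val, np.generic):
            val = val.item()
        out[key] = val
    return out


def _open(path_or_file, mode):
    if isinstance(path_or_file, h5py.File):
        return path_or_file, False
    return h5py.File(path_or_file, mode), True


# ---------------------------------------------------------------------------
# Traces and stacks
# ---------------------------------------------------------------------------

def write_trace(path, trace: PhotonTrace, name: str = "trace") -> None:
    f, close = _open(path, "a")
    try:
        grp = f.require_group("traces").create_group(name)
        dset = grp.create_dataset("counts", data=np.asarray(trace.counts,
                                                            dtype=np.int64))
        dset.attrs["units"] = "counts"
        _stamp(grp, {"bin_dt": trace.bin_dt, "t_start": trace.t_start,
                     **trace.attrs})
    finally:
        if close:
            f.close()


def read_trace(path, name: str = "trace") -> PhotonTrace:
    f, close = _open(path, "r")
    try:
        grp = f["traces"][name]
        _check_version(grp)
        attrs = _load_attrs(grp, skip=("bin_dt", "t_start"))
        return PhotonTrace(counts=grp["counts"][()],
                           bin_dt=float(grp.attrs["bin_dt"]),
                           t_start=float(grp.attrs["t_start"]), attrs=attrs)
    finally:
        if close:
            f.close()


_GEOM_KEYS = ("t_pix", "t_line", "s_xi", "s_psi", "s_zeta", "alpha",
              "n_cols", "n_rows")


def write_stack(path, stack: ImageStack, name: str = "stack") -> None:
    f, close = _open(path, "a")
    try:
        grp = f.require_group("images").create_group(name)
        dset = grp.create_dataset("frames",
                                  data=np.asarray(stack.frames,
                                                  dtype=np.int64))
        dset.attrs["units"] = "counts"
        geom = {k: getattr(stack.geometry, k) for k in _GEOM_KEYS}
        _stamp(grp, {**geom, **stack.attrs})
    finally:
        if close:
            f.close()


def read_stack(path, name: str = "stack") -> ImageStack:
    f, close = _open(path, "r")
    try:
        grp = f["images"][name]
        _check_version(grp)
        geom = ScanGeometry(**{k: grp.attrs[k].item()
                               if isinstance(grp.attrs[k], np.generic)
                               else grp.attrs[k] for k in _GEOM_KEYS})
        attrs = _load_attrs(grp, skip=_GEOM_KEYS)
        return ImageStack(frames=grp["frames"][()], geometry=geom,
                          attrs=attrs)
    finally:
        if close:
            f.close()


# ---------------------------------------------------------------------------
# ACFs
# ---------------------------------------------------------------------------

def write_acf(path, acf, name: str = "acf") -> None:
    f, close = _open(path, "a")
    try:
        if isinstance(acf, AcfCurve):
            grp = f.require_group("acf").create_group(name)
            grp.create_dataset("lags", data=acf.lags).attrs["units"] = "s"
            grp.create_dataset("g", data=acf.g)
            if acf.sigma is not None:
                grp.create_dataset("sigma", data=acf.sigma)
            _stamp(grp, {"n_traces": acf.n_traces, **acf.attrs})
        elif isinstance(acf, Acf2D):
            grp = f.require_group("acf2d").create_group(name)
            grp.create_dataset("g", data=acf.g)
            grp.create_dataset("xi_range", data=acf.xi_range)
            grp.create_dataset("psi_range", data=acf.psi_range)
            if acf.sigma is not None:
                grp.create_dataset("sigma", data=acf.sigma)
            geom = {k: getattr(acf.geometry, k) for k in _GEOM_KEYS}
            _stamp(grp, {**geom, "n_frames": acf.n_frames, **acf.attrs})
        else:
            raise TypeError("expected AcfCurve or Acf2D")
    finally:
        if close:
            f.close()


def read_acf(path, name: str = "acf"):
    f, close = _open(path, "r")
    try:
        if "acf" in f and name in f["acf"]:
            grp = f["acf"][name]
            _check_version(grp)
            attrs = _load_attrs(grp, skip=("n_traces",))
            return AcfCurve(lags=grp["lags"][()], g=grp["g"][()],
                            sigma=grp["sigma"][()] if "sigma" in grp else None,
                            n_traces=int(grp.attrs["n_traces"]), attrs=attrs)
        grp = f["acf2d"][name]
        _check_version(grp)
        geom = ScanGeometry(**{k: grp.attrs[k].item()
                               if isinstance(grp.attrs[k], np.generic)
                               else grp.attrs[k] for k in _GEOM_KEYS})
        attrs = _load_attrs(grp, skip=_GEOM_KEYS + ("n_frames",))
        return Acf2D(g=grp["g"][()], xi_range=grp["xi_range"][()],
                     psi_range=grp["psi_range"][()], geometry=geom,
                     sigma=grp["sigma"][()] if "sigma" in grp else None,
                     n_frames=int(grp.attrs["n_frames"]), attrs=attrs)
    finally:
        if close:
            f.close()


# ---------------------------------------------------------------------------
# PSF grids
# ---------------------------------------------------------------------------

def write_psf(path, grid: PsfGrid, name: str = "psf") -> None:
    f, close = _open(path, "a")
    try:
        grp = f.require_group("psf").create_group(name)
        grp.create_dataset("values", data=grid.values)
        _stamp(grp, {"voxel": list(grid.voxel), **grid.attrs})
    finally:
        if close:
            f.close()


def read_psf(path, name: str = "psf") -> PsfGrid:
    f, close = _open(path, "r")
    try:
        grp = f["psf"][name]
        _check_version(grp)
        attrs = _load_attrs(grp, skip=("voxel",))
        return PsfGrid(values=grp["values"][()],
                       voxel=tuple(np.asarray(grp.attrs["voxel"],
                                              dtype=float)), attrs=attrs)
    finally:
        if close:
            f.close()


def read_bead_tiff(path, voxel) -> PsfGrid:
    """Read a bead z-stack from TIFF as a PsfGrid (pages = z planes).

    TIFF pages arrive as (z, y, x); the grid is transposed to (x, y, z).
    """
    import tifffile
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return PsfGrid(values=np.transpose(arr, (2, 1, 0)), voxel=tuple(voxel))


# ---------------------------------------------------------------------------
# Fit results and posteriors
# ---------------------------------------------------------------------------

def write_fit(path, fit: FitResult, name: str = "fit") -> None:
    f, close = _open(path, "a")
    try:
        grp = f.require_group("fits").create_group(name)
        grp.create_dataset("theta", data=fit.theta)
        grp.create_dataset("stderr", data=fit.stderr)
        grp.create_dataset("residuals", data=fit.residuals)
        grp.create_dataset("residuals_transformed",
                           data=fit.residuals_transformed)
        _stamp(grp, {"param_names": json.dumps(fit.param_names),
                     "ssr": fit.ssr, "chi2": fit.chi2,
                     "chi2_red": fit.chi2_red, "n": fit.n, "p": fit.p,
                     "converged": fit.converged,
                     "error_mode": fit.error_mode, **fit.attrs})
    finally:
        if close:
            f.close()


def read_fit(path, name: str = "fit") -> FitResult:
    f, close = _open(path, "r")
    try:
        grp = f["fits"][name]
        _check_version(grp)
        skip = ("param_names", "ssr", "chi2", "chi2_red", "n", "p",
                "converged", "error_mode")
        attrs = _load_attrs(grp, skip=skip)
        return FitResult(
            param_names=json.loads(grp.attrs["param_names"]),
            theta=grp["theta"][()], stderr=grp["stderr"][()],
            ssr=float(grp.attrs["ssr"]), chi2=float(grp.attrs["chi2"]),
            chi2_red=float(grp.attrs["chi2_red"]), n=int(grp.attrs["n"]),
            p=int(grp.attrs["p"]), residuals=grp["residuals"][()],
            residuals_transformed=grp["residuals_transformed"][()],
            converged=bool(grp.attrs["converged"]),
            error_mode=str(grp.attrs["error_mode"]), attrs=attrs)
    finally:
        if close:
            f.close()


def export_posterior(post: PosteriorResult, path) -> None:
    """Write a posterior to a NetCDF file (classic format).

    Equal-weight posterior draws are stored as ``posterior_<param>`` over
    dimensions (chain, draw); log-likelihood bookkeeping is not stored
    (the sampler reports only the evidence).  log_z and log_z_err are
    global attributes.
    """
    import xarray as xr
    n = post.samples.shape[0]
    data_vars = {
        "posterior_" + nm: (("chain", "draw"),
                            post.samples[:, i][None, :])
        for i, nm in enumerate(post.param_names)
    }
    data_vars["sample_stats_weights"] = (("chain", "draw"),
                                         np.full((1, n), 1.0 / n))
    ds = xr.Dataset(
        data_vars,
        coords={"chain": [0], "draw": np.arange(n)},
        attrs={"log_z": post.log_z, "log_z_err": post.log_z_err,
               "error_mode": post.error_mode, "n_data": post.n_data,
               "software": _SOFTWARE, "schema_version": SCHEMA_VERSION,
               "param_names": json.dumps(post.param_names)},
    )
    ds.to_netcdf(path, engine="scipy")


def read_posterior(path) -> PosteriorResult:
    import xarray as xr
    with xr.open_dataset(path, engine="scipy") as ds:
        names = json.loads(ds.attrs["param_names"])
        samples = np.column_stack(
            [np.asarray(ds["posterior_" + nm][0]) for nm in names])
        return PosteriorResult(
            param_names=names, samples=samples,
            log_z=float(ds.attrs["log_z"]),
            log_z_err=float(ds.attrs["log_z_err"]),
            n_data=int(ds.attrs["n_data"]),
            error_mode=str(ds.attrs["error_mode"]))
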