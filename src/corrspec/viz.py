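"""Figure generation for every analysis stage (non-interactive, Agg).

Each function takes in-memory objects, draws onto a fresh figure and, when
``path`` is given, saves both vector (.pdf) and raster (.png) files.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def _save(fig, path):
    if path is not None:
        root = str(path)
        for ext in (".png", ".pdf"):
            if root.endswith(ext):
                root = root[:-len(ext)]
        fig.savefig(root + ".png", dpi=150)
        fig.savefig(root + ".pdf")
        plt.close(fig)
    return fig


def plot_trace(trace, bin_width: float = 0.01, window=None, path=None):
    """Photon rate vs time (kcounts/s) after coarse binning."""
    stride = max(1, int(round(bin_width / trace.bin_dt)))
    n = trace.counts.size // stride
    rate = trace.counts[:n * stride].reshape(n, stride).sum(axis=1) \
        / (stride * trace.bin_dt) / 1e3
    t = trace.t_start + (np.arange(n) + 0.5) * stride * trace.bin_dt
    fig, ax = plt.subplots()
    ax.plot(t, rate, lw=0.5)
    if window is not None:
        for x in window:
            ax.axvline(x, color="r", ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("photon rate (kcounts/s)")
    return _save(fig, path)


def plot_acf(acf, log_x: bool = True, fit_curve=None, bands=None, path=None):
    """ACF vs lag time; optional median fit line and shaded quantile bands."""
    fig, axes = plt.subplots(
        2 if fit_curve is not None else 1, 1, sharex=True,
        gridspec_kw={"height_ratios": [3, 1]} if fit_curve is not None else None)
    ax = axes[0] if fit_curve is not None else axes
    ax.errorbar(acf.lags, acf.g, yerr=acf.sigma, fmt="o", ms=3,
                lw=0.8, label="ACF")
    if fit_curve is not None:
        ax.plot(acf.lags, fit_curve, "k-", label="median fit")
        resid = acf.g - fit_curve
        axr = axes[1]
        axr.axhline(0, color="0.6", lw=0.5)
        if bands:
            for lev, (lob, hib) in sorted(bands.items(), reverse=True):
                shade = "0.75" if lev > 0.9 else "0.45"
                ax.fill_between(acf.lags, lob, hib, color=shade, alpha=0.6)
                axr.fill_between(acf.lags, lob - fit_curve, hib - fit_curve,
                                 color=shade, alpha=0.6)
        axr.plot(acf.lags, resid, "k-", lw=0.8)
        axr.set_ylabel("residual")
        axr.set_xlabel("lag time τ (s)")
    else:
        ax.set_xlabel("lag time τ (s)")
    if log_x:
        ax.set_xscale("log")
    ax.set_ylabel("G(τ)")
    ax.legend(frameon=False)
    return _save(fig, path)


def plot_acf_heatmap(acf2d, path=None):
    """2-D spatial ACF as a heatmap over (ξ, ψ)."""
    fig, ax = plt.subplots()
    extent = [acf2d.xi_range[0] - 0.5, acf2d.xi_range[-1] + 0.5,
              acf2d.psi_range[-1] + 0.5, acf2d.psi_range[0] - 0.5]
    im = ax.imshow(acf2d.g, extent=extent, aspect="auto", cmap="viridis")
    fig.colorbar(im, ax=ax, label="G(ξ, ψ)")
    ax.set_xlabel("pixel lag ξ")
    ax.set_ylabel("line lag ψ")
    return _save(fig, path)


def plot_covariance(cov, path=None):
    """Heatmap of the empirical lag covariance matrix."""
    fig, ax = plt.subplots()
    vmax = np.percentile(np.abs(cov), 99)
    im = ax.imshow(cov, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, label="Σᵢⱼ")
    ax.set_xlabel("lag index j")
    ax.set_ylabel("lag index i")
    return _save(fig, path)


def plot_posterior(results: dict, param: str = "dc", path=None):
    """Overlayed posterior histograms (e.g. OLS vs WLS vs GLS) with median
    dashed lines."""
    fig, ax = plt.subplots()
    for label, post in results.items():
        col = post.samples[:, post.param_names.index(param)]
        ax.hist(col, bins=60, density=True, histtype="step", label=label)
        ax.axvline(np.median(col), ls="--", lw=0.8)
    ax.set_xlabel(param)
    ax.set_ylabel("posterior density")
    ax.legend(frameon=False)
    return _save(fig, path)


def plot_corner(post, path=None):
    """Pairwise posterior scatter / marginal histograms."""
    names = post.param_names
    k = len(names)
    fig, axes = plt.subplots(k, k, figsize=(2 * k, 2 * k))
    axes = np.atleast_2d(axes)
    for i in range(k):
        for j in range(k):
            ax = axes[i, j]
            if j > i:
                ax.axis("off")
                continue
            if i == j:
                ax.hist(post.samples[:, i], bins=40, histtype="step")
            else:
                ax.plot(post.samples[:, j], post.samples[:, i], ",",
                        alpha=0.3)
            if i == k - 1:
                ax.set_xlabel(names[j])
            if j == 0 and i > 0:
                ax.set_ylabel(names[i])
    fig.tight_layout()
    return _save(fig, path)


def plot_map(pmap, path=None):
    """Parameter map with a physical-unit color bar."""
    fig, ax = plt.subplots()
    extent = [pmap.centers_x[0], pmap.centers_x[-1],
              pmap.centers_y[-1], pmap.centers_y[0]]
    im = ax.imshow(pmap.grid, extent=extent, cmap="viridis")
    label = pmap.name + (" (%s)" % pmap.units if pmap.units else "")
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    return _save(fig, path)


def plot_angular(rows, path=None):
    """DC estimates vs scan angle with error bars."""
    fig, ax = plt.subplots()
    angles = [r["angle"] for r in rows]
    for key in rows[0]:
        if key.startswith("dc") and not key.endswith("_err"):
            vals = [r[key] for r in rows]
            errs = [r.get(key + "_err", 0) for r in rows]
            ax.errorbar(angles, vals, yerr=errs, marker="o", label=key)
    ax.set_xlabel("scan angle α (deg)")
    ax.set_ylabel("DC (μm²/s)")
    ax.legend(frameon=False)
    return _save(fig, path)
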