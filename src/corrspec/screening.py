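"""Pre- and post-ACF quality control.

Stability screening drops leading traces/frames whose running mean drifts
from the tail level (bleaching, stage settling); attribute filters select
acquisition conditions (scan angle, speed, free-form keys); the DC–C
pre-analysis runs a fast single-component OLS fit on every individual
ACF and excludes outliers before the pooled main fit.  The pre-analysis
fit is a screening statistic, not an estimate: it always uses the simplest
compatible model (isotropic single component, no triplet) for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import ErrorModel, ModelSpec, PriorSpec
from .inference import fit_nls


@dataclass
class FilterSpec:
    """Declarative selection of traces/frames/ACFs.

    ``attributes`` maps attribute keys to the set of allowed values;
    ``dc_range``/``c_range`` bound the pre-analysis estimates (μm²/s, nM).
    """

    time_window: Optional[tuple] = None
    frame_range: Optional[tuple] = None
    attributes: dict = field(default_factory=dict)
    dc_range: Optional[tuple] = None
    c_range: Optional[tuple] = None

    def __post_init__(self) -> None:
        for rng in (self.time_window, self.frame_range, self.dc_range,
                    self.c_range):
            if rng is not None and not rng[0] < rng[1]:
                raise ValueError("ranges must be well-ordered (lo < hi)")

    def match_attrs(self, attrs: dict) -> bool:
        for key, allowed in self.attributes.items():
            if key not in attrs:
                raise KeyError("filter references missing attribute %r" % key)
            if attrs[key] not in allowed:
                return False
        return True


def select_stable(items, criterion: float = 0.10, indices=None,
                  summary=np.mean):
    """Drop the unstable leading portion of a sequence of traces or frames.

    Each item is reduced to a scalar intensity with ``summary``; leading
    items whose running mean deviates from the mean of the trailing half by
    more than ``criterion`` (fraction) are dropped.  Alternatively an
    explicit ``indices`` list selects items directly.

    Returns ``(kept_items, report)`` where the report lists every item as
    kept or dropped.
    """
    items = list(items)
    if not items:
        raise ValueError("empty input")
    if indices is not None:
        keep = set(int(i) for i in indices)
        report = [{"index": i, "kept": i in keep,
                   "reason": None if i in keep else "manual exclusion"}
                  for i in range(len(items))]
        kept = [items[i] for i in sorted(keep)]
        if not kept:
            raise ValueError("manual selection excluded everything")
        return kept, report

    levels = np.array([float(summary(np.asarray(it))) for it in items])
    tail = levels[len(levels) // 2:]
    ref = tail.mean()
    if ref == 0:
        raise ValueError("zero reference intensity")
    # running mean of the remaining sequence after cutting a prefix of
    # length k; drop the shortest prefix that brings it within tolerance
    suffix_mean = (np.cumsum(levels[::-1])[::-1]
                   / np.arange(len(levels), 0, -1))
    bad = np.abs(suffix_mean - ref) > criterion * abs(ref)
    first_good = 0
    while first_good < len(items) and bad[first_good]:
        first_good += 1
    if first_good == len(items):
        raise ValueError("stability rule excluded every item")
    report = [{"index": i, "kept": i >= first_good,
               "reason": None if i >= first_good else
               "running mean deviates >%.0f%% from tail" % (100 * criterion)}
              for i in range(len(items))]
    return items[first_good:], report


def filter_by_attributes(items, spec: FilterSpec):
    """Keep items whose ``attrs`` match every attribute predicate."""
    kept, report = [], []
    for i, it in enumerate(items):
        ok = spec.match_attrs(getattr(it, "attrs", {}))
        report.append({"index": i, "kept": ok,
                       "reason": None if ok else "attribute filter"})
        if ok:
            kept.append(it)
    return kept, report


def preanalyze_dc_c(items, psf, priors: PriorSpec = None,
                    dc_range=None, c_range=None, k_mad: float = 5.0):
    """Quick per-item DC/C estimates and outlier exclusion.

    Fits each ACF with the isotropic single-component model under OLS and
    flags items outside explicit ``dc_range``/``c_range`` or, when no
    ranges are given, beyond ``k_mad``·MAD of the cohort median.

    Returns ``(kept_items, table)``; the table has one row per input item
    with columns item, dc, c, kept, reason.
    """
    if not items:
        raise ValueError("need at least one ACF")
    spec = ModelSpec(kind="iso1", triplet=False)
    rows = []
    for i, item in enumerate(items):
        try:
            fit = fit_nls(item, spec, psf, ErrorModel(mode="OLS"),
                          priors or PriorSpec())
            rows.append({"item": i, "dc": fit["dc"], "c": fit["c"],
                         "kept": True, "reason": None})
        except Exception as exc:  # per-item failure is a data property
            rows.append({"item": i, "dc": np.nan, "c": np.nan,
                         "kept": False, "reason": "fit failed: %s" % exc})

    ok = [r for r in rows if r["kept"]]
    for key, rng in (("dc", dc_range), ("c", c_range)):
        vals = np.array([r[key] for r in ok])
        if rng is not None:
            lo, hi = rng
        else:
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            lo, hi = med - k_mad * mad, med + k_mad * mad
            if mad == 0:
                continue
        for r in ok:
            if r["kept"] and not lo <= r[key] <= hi:
                r["kept"] = False
                r["reason"] = "%s=%.3g outside [%.3g, %.3g]" % (key, r[key],
                                                                lo, hi)
    kept = [items[r["item"]] for r in rows if r["kept"]]
    return kept, rows
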