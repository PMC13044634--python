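"""Shared fixtures: Gaussian PSF, synthetic traces and the multitrace
cohort used by the statistically heavy recovery tests.

The cohort emulates dilute-solution point-FCS replicates (25 particles in
an 8 × 8 × 12 μm box, DC = 20 μm²/s) at a desk-scale cohort size; it is
session-scoped because the Brownian-dynamics simulation dominates the
suite's runtime.
"""

import warnings

import numpy as np
import pytest

import corrspec as cs
from corrspec.datatypes import SimConfig


@pytest.fixture(scope="session")
def gauss_psf():
    return cs.GaussianPsf(0.3, 0.3, 1.1)


@pytest.fixture(scope="session")
def single_trace():
    """One synthetic point-FCS trace at the standard single-trace settings
    (100 particles, 2.5 × 2.5 × 7 μm box, DC = 100 μm²/s, dt = 1 μs),
    desk-scaled to 10 s."""
    cfg = SimConfig(n_particles=100, box=(2.5, 2.5, 7.0),
                    dc_true=(100.0,) * 3, duration=10.0, dt=1e-6, seed=42)
    return cs.simulate_fcs_trace(cfg), cfg


@pytest.fixture(scope="session")
def cohort():
    """48 independent 20-s traces (DC = 20 μm²/s), log-binned ACFs and the
    empirical lag covariance."""
    curves = []
    first_dense = None
    for s in range(48):
        cfg = SimConfig(n_particles=25, box=(8.0, 8.0, 12.0),
                        dc_true=(20.0,) * 3, duration=20.0, dt=5e-6,
                        seed=1000 + s)
        trace = cs.simulate_fcs_trace(cfg)
        acf = cs.acf_fcs(trace, max_lag=0.1)
        if first_dense is None:
            # finely binned single-trace curve for the OLS model-selection
            # check (single-trace fits conventionally keep ~100 points)
            first_dense = cs.crop_and_downsample(acf, drop_first=1,
                                                 log_bins=100)
        curves.append(cs.crop_and_downsample(acf, drop_first=1, log_bins=20))
    mean = cs.mean_acf(curves)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        em = cs.estimate_covariance(curves)
    return {"curves": curves, "mean": mean, "em": em,
            "first_dense": first_dense, "dc_true": 20.0,
            "c_true_nm": cs.molecules_to_nm(25 / (8 * 8 * 12))}
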