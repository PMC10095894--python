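"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from quenchbind.spectra_io import TitrationPoint, TitrationSeries
from quenchbind.synthetic import GroundTruth, PanelDesign, generate_panel


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations; kept separate from
# the package code paths they are used to check).


def ols_oracle(x, y):
    """Textbook least squares via the normal equations through numpy.polyfit."""
    slope, intercept = np.polyfit(x, y, 1)
    sse = float(np.sum((y - intercept - slope * x) ** 2))
    return intercept, slope, sse


def brute_force_breakpoint(x, y, min_segment=3):
    """Enumerate every breakpoint; return (best_k, best_sse, single_sse).

    Ties resolve to the earliest breakpoint, scanning in increasing k.
    """
    n = len(x)
    _, _, single_sse = ols_oracle(x, y)
    best_k, best_sse = None, np.inf
    for k in range(min_segment, n - min_segment + 1):
        _, _, sse_l = ols_oracle(x[:k], y[:k])
        _, _, sse_r = ols_oracle(x[k:], y[k:])
        if sse_l + sse_r < best_sse:
            best_k, best_sse = k, sse_l + sse_r
    return best_k, best_sse, single_sse


def bisection_free_ligand(K1, K2, P, Qt, iterations=200):
    """Plain bisection on the two-site mass balance."""
    def resid(qf):
        return qf + P * (K1 * qf / (1 + K1 * qf) + K2 * qf / (1 + K2 * qf)) - Qt

    lo, hi = 0.0, Qt
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def noiseless_truth() -> GroundTruth:
    return GroundTruth(noise_cv=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_panel(noiseless_truth):
    """(titration, absorbance, truth dict) for the default noiseless panel."""
    return generate_panel(noiseless_truth, PanelDesign())


def make_series(q, f, condition="free", temperature=25.0, **kwargs):
    points = tuple(
        TitrationPoint(quencher_total=float(qi), intensity=float(fi))
        for qi, fi in zip(q, f)
    )
    return TitrationSeries(
        condition=condition, temperature=temperature, points=points, **kwargs
    )


@pytest.fixture
def single_site_series():
    """Exact single-site dark-complex titration: F = F0/(1 + K*Q), K = 5.9e5."""
    K, f0 = 5.9e5, 1000.0
    q = np.arange(0, 11) * 1e-6
    return make_series(q, f0 / (1 + K * q)), K
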