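"""Shared fixtures and independent oracle helpers.

The oracle functions here deliberately re-derive quantities by brute force
(dense-grid quadrature, residual scanning, textbook formulas) so that the
package implementations are checked against code that shares nothing with
them beyond the problem statement.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_gaussian_moments(theta0_deg: float, sigma_deg: float,
                            npts: int = 2_000_001):
    """Dense-grid trapezoid moments of the reflected gaussian-on-sphere."""
    t0 = np.radians(theta0_deg)
    s = np.radians(sigma_deg)
    th = np.linspace(0.0, np.pi, npts)
    g = np.zeros_like(th)
    for n in range(-2, 3):
        for tc in (t0, -t0):
            g += np.exp(-((th - tc - 2.0 * np.pi * n) ** 2) / (2.0 * s * s))
    w = g * np.sin(th)
    c = np.cos(th)
    norm = np.trapezoid(w, th)
    return (np.trapezoid(c ** 2 * w, th) / norm,
            np.trapezoid(c ** 4 * w, th) / norm)


def oracle_intensities_by_integration(dist, scale: float, npts: int = 2_000_001):
    """Polarized components by direct numerical integration against a
    distribution: i_pp ~ <cos^4>, i_cross ~ <cos^2 sin^2>/2, i_tt ~ 3/8<sin^4>.
    Handles delta, gaussian_on_sphere and mixture kinds independently of the
    package's moment machinery."""
    def weights(d):
        if d.kind == "delta":
            t0 = np.radians(d.theta0)
            c, s = np.cos(t0), np.sin(t0)
            return c ** 4, (c * s) ** 2 / 2.0, 0.375 * s ** 4
        if d.kind == "mixture":
            acc = np.zeros(3)
            for w, sub in d.components:
                acc += w * np.array(weights(sub))
            return tuple(acc)
        t0 = np.radians(d.theta0)
        sg = np.radians(d.sigma)
        th = np.linspace(0.0, np.pi, npts)
        g = np.zeros_like(th)
        for n in range(-2, 3):
            for tc in (t0, -t0):
                g += np.exp(-((th - tc - 2.0 * np.pi * n) ** 2) / (2.0 * sg * sg))
        w = g * np.sin(th)
        c, s = np.cos(th), np.sin(th)
        norm = np.trapezoid(w, th)
        return (np.trapezoid(c ** 4 * w, th) / norm,
                np.trapezoid((c * s) ** 2 * w, th) / norm / 2.0,
                0.375 * np.trapezoid(s ** 4 * w, th) / norm)

    i_pp, i_x, i_tt = weights(dist)
    return scale * i_pp, scale * i_x, scale * i_tt


def oracle_free_ca_scan(recipe, n_bisect: int = 200) -> float:
    """Free Ca by an independent transcription of the mass balance and a
    plain interval-halving scan of the residual sign."""
    def total(ca):
        egta = recipe.total_egta / (
            1 + recipe.k_ca_egta * ca + recipe.k_mg_egta * recipe.free_mg)
        atp = recipe.total_atp / (
            1 + recipe.k_ca_atp * ca + recipe.k_mg_atp * recipe.free_mg)
        return ca * (1 + recipe.k_ca_egta * egta + recipe.k_ca_atp * atp)

    lo, hi = 0.0, recipe.total_ca
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if total(mid) > recipe.total_ca:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def oracle_paired_t(a, b):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)), d = b - a."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return t, p


def random_feasible_order_params(rng, n: int):
    """Uniform samples from the feasible (p2, p4) region via (m2, m4)."""
    m2 = rng.uniform(0.0, 1.0, n)
    m4 = rng.uniform(m2 ** 2, m2)
    p2 = (3.0 * m2 - 1.0) / 2.0
    p4 = (35.0 * m4 - 30.0 * m2 + 3.0) / 8.0
    return p2, p4


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture(scope="session")
def noiseless_cohort():
    from fiberpol.simulate import NoiseModel, generate_cohort
    return generate_cohort(2, noise=NoiseModel.zero(), master_seed=11)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    from fiberpol.simulate import generate_cohort
    return generate_cohort(5, master_seed=42)
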