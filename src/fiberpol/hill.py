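"""Hill-equation fitting of pCa titrations of force or ``<P2>``.

The response model is::

    Y(pCa) = baseline + amplitude / (1 + 10**(n_h * (pCa - pca50)))

where ``pca50`` is the pCa of half-maximal change, ``n_h`` the Hill
coefficient, ``baseline`` the relaxed (high-pCa) plateau and ``amplitude``
the signed total change on full activation (negative for responses that
decrease with Ca2+).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationCurve",
    "HillParameters",
    "hill_fraction",
    "hill_eval",
    "fit_hill",
    "delta_p2",
]

NH_BOUNDS = (0.5, 10.0)
PCA50_MARGIN = 0.5
MIN_POINTS = 5


@dataclass
class TitrationCurve:
    """Per-trabecula (pCa, response) series with condition metadata."""

    pca: np.ndarray
    response: np.ndarray
    response_kind: str = "p2"          # "p2" or "force"
    probe: str = "none"                # cTnC-C, cTnC-E, cRLC-BC, none
    sl_um: float = float("nan")
    treatment: str = "control"
    trabecula_id: str = ""

    def __post_init__(self) -> None:
        self.pca = np.asarray(self.pca, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.pca.shape != self.response.shape or self.pca.ndim != 1:
            raise ValueError("pca and response must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.pca)):
            raise ValueError("pca values must be finite")

    def __len__(self) -> int:
        return self.pca.size


@dataclass
class HillParameters:
    pca50: float
    n_h: float
    baseline: float
    amplitude: float
    se_pca50: float = float("nan")
    se_nh: float = float("nan")
    se_baseline: float = float("nan")
    se_amplitude: float = float("nan")
    converged: bool = True
    degenerate: bool = False       # amplitude indistinguishable from 0 at 2 sigma

    def __post_init__(self) -> None:
        if self.n_h <= 0:
            raise ValueError("n_h must be positive")


def hill_fraction(pca, pca50: float, n_h: float):
    """Activation fraction ``1 / (1 + 10**(n_h*(pca - pca50)))`` in [0, 1]."""
    return 1.0 / (1.0 + 10.0 ** (n_h * (np.asarray(pca, dtype=float) - pca50)))


def hill_eval(params: HillParameters, pca):
    """Evaluate the Hill model at one or more pCa values."""
    return params.baseline + params.amplitude * hill_fraction(
        pca, params.pca50, params.n_h
    )


def _init_guess(pca: np.ndarray, resp: np.ndarray) -> tuple[float, float, float]:
    """(pca50, baseline, amplitude) starting values from plateaus and the
    midpoint crossing of a monotone-in-pCa interpolation."""
    order = np.argsort(pca)[::-1]          # high pCa (relaxed) first
    p, r = pca[order], resp[order]
    k = max(1, min(2, p.size // 3))
    baseline = float(np.mean(r[:k]))
    top = float(np.mean(r[-k:]))
    amplitude = top - baseline
    target = baseline + amplitude / 2.0
    pca50 = float(np.median(p))
    for i in range(p.size - 1):
        lo, hi = sorted((r[i], r[i + 1]))
        if lo <= target <= hi and r[i + 1] != r[i]:
            frac = (target - r[i]) / (r[i + 1] - r[i])
            pca50 = float(p[i] + frac * (p[i + 1] - p[i]))
            break
    return pca50, baseline, amplitude


def fit_hill(
    curve: TitrationCurve,
    fix_baseline: Optional[float] = None,
    normalize: bool = False,
) -> HillParameters:
    """Nonlinear least-squares Hill fit with standard errors.

    Force curves are conventionally fit with ``fix_baseline=0``.  With
    ``normalize=True`` the reported baseline/amplitude (and their SEs) are
    divided by the fitted saturation response, so force curves read as a
    fraction of fitted maximum; ``pca50`` and ``n_h`` are unaffected.

    Flat curves whose fitted amplitude is indistinguishable from zero at two
    standard errors are returned with ``degenerate=True``, never raised.
    """
    if len(curve) < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {len(curve)}")
    if np.unique(curve.pca).size < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} distinct pCa points")

    pca, resp = curve.pca, curve.response
    pca50_0, base_0, amp_0 = _init_guess(pca, resp)
    lo_pca, hi_pca = pca.min() - PCA50_MARGIN, pca.max() + PCA50_MARGIN
    pca50_0 = float(np.clip(pca50_0, lo_pca, hi_pca))
    if amp_0 == 0.0:
        amp_0 = (np.ptp(resp) or 1.0)

    if fix_baseline is None:
        def model(x, pca50, n_h, baseline, amplitude):
            return baseline + amplitude * hill_fraction(x, pca50, n_h)
        p0 = [pca50_0, 3.0, base_0, amp_0]
        bounds = (
            [lo_pca, NH_BOUNDS[0], -np.inf, -np.inf],
            [hi_pca, NH_BOUNDS[1], np.inf, np.inf],
        )
    else:
        def model(x, pca50, n_h, amplitude):
            return fix_baseline + amplitude * hill_fraction(x, pca50, n_h)
        p0 = [pca50_0, 3.0, amp_0 + base_0 - fix_baseline]
        bounds = (
            [lo_pca, NH_BOUNDS[0], -np.inf],
            [hi_pca, NH_BOUNDS[1], np.inf],
        )

    try:
        popt, pcov = curve_fit(
            model, pca, resp, p0=p0, bounds=bounds,
            maxfev=20000, xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        converged = True
    except RuntimeError:
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.nan)
        converged = False

    se = np.sqrt(np.diag(pcov))
    if fix_baseline is None:
        pca50, n_h, baseline, amplitude = popt
        se_pca50, se_nh, se_base, se_amp = se
    else:
        pca50, n_h, amplitude = popt
        baseline, se_base = fix_baseline, 0.0
        se_pca50, se_nh, se_amp = se

    degenerate = bool(
        np.isfinite(se_amp) and abs(amplitude) <= 2.0 * se_amp
    )

    if normalize:
        # saturation response for fixed-baseline (force) fits, else the span
        if fix_baseline is not None:
            span = abs(baseline + amplitude)
        else:
            span = abs(amplitude)
        if span > 0:
            baseline, amplitude = baseline / span, amplitude / span
            se_base, se_amp = se_base / span, se_amp / span

    return HillParameters(
        pca50=float(pca50), n_h=float(n_h),
        baseline=float(baseline), amplitude=float(amplitude),
        se_pca50=float(se_pca50), se_nh=float(se_nh),
        se_baseline=float(se_base), se_amplitude=float(se_amp),
        converged=converged, degenerate=degenerate,
    )


def delta_p2(
    curve: TitrationCurve, pca_relaxed: float = 6.0, pca_active: float = 4.5,
    atol: float = 1e-9,
) -> float:
    """Signed activation change: response(pCa 4.5) - response(pCa 6).

    Both anchor pCa values must be present in the curve (averaged if
    replicated).  Per-trabecula values are averaged by the caller, matching
    the paired experimental design.
    """
    def anchor(target: float) -> float:
        mask = np.abs(curve.pca - target) <= atol
        if not mask.any():
            raise ValueError(f"curve has no measurement at pCa {target}")
        return float(curve.response[mask].mean())

    return anchor(pca_active) - anchor(pca_relaxed)
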