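"""Static uniaxial optical model for dipole populations in a fiber.

Links an axial-angle distribution of fluorescence dipoles to the four
polarized intensity components measured with excitation and emission
polarizers parallel/perpendicular to the fiber axis, and inverts measured
intensities to the order parameters ``<P2>`` and ``<P4>``.

Conventions
-----------
* theta is the polar angle between a dipole and the fiber axis; the
  population is assumed uniaxially symmetric about that axis and static on
  the emission timescale (absorption and emission dipoles parallel).
* ``m2 = <cos^2 theta>`` and ``m4 = <cos^4 theta>`` are the raw moments;
  ``p2 = (3 m2 - 1)/2`` and ``p4 = (35 m4 - 30 m2 + 3)/8`` are the Legendre
  order parameters.  ``p2`` is +1 when every dipole is parallel to the axis
  and -0.5 when all are perpendicular.
* Angles are degrees at every public interface, radians internally.
* An optional fast-wobble order parameter ``p2d`` is carried as metadata
  only; it never enters the forward model here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

__all__ = [
    "AngleDistribution",
    "Moments",
    "OrderParameterSet",
    "PolarizedIntensitySet",
    "InversionResult",
    "moments_from_distribution",
    "order_params_from_moments",
    "moments_from_order_params",
    "forward_intensities",
    "invert_intensities",
    "apply_attenuation",
    "mixture_p2",
    "project_moments",
]

#: absolute tolerance for quadrature of the moment integrals
_QUAD_EPSABS = 1e-12
#: slack allowed when checking moment feasibility (numerical noise only)
_FEAS_TOL = 1e-9


class FeasibilityError(ValueError):
    """An (m2, m4) or (p2, p4) pair outside the physically realizable set."""


# ---------------------------------------------------------------------------
# distributions and moments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngleDistribution:
    """Axial-angle distribution of a dipole population.

    Parameters
    ----------
    kind:
        ``"delta"`` (all dipoles at ``theta0``), ``"gaussian_on_sphere"``
        (density proportional to ``exp(-(theta-theta0)^2/(2 sigma^2)) *
        sin(theta)`` on [0, 180] degrees, reflected at both boundaries), or
        ``"mixture"`` of weighted sub-distributions.
    theta0:
        Mean polar angle in degrees, within [0, 90].
    sigma:
        Angular dispersion in degrees; required and > 0 for
        ``gaussian_on_sphere``, must be absent for ``delta``.
    components:
        For ``kind="mixture"``: sequence of ``(weight, AngleDistribution)``
        with non-negative weights summing to 1.
    """

    kind: str
    theta0: float = 0.0
    sigma: Optional[float] = None
    components: Optional[Sequence[tuple]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "gaussian_on_sphere", "mixture"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "mixture":
            if not self.components:
                raise ValueError("mixture requires components")
            weights = np.array([w for w, _ in self.components], dtype=float)
            if np.any(weights < 0):
                raise ValueError("mixture weights must be non-negative")
            if abs(weights.sum() - 1.0) > 1e-12:
                raise ValueError(
                    f"mixture weights must sum to 1 (got {weights.sum()!r})"
                )
            return
        if not (0.0 <= self.theta0 <= 90.0):
            raise ValueError("theta0 must lie in [0, 90] degrees")
        if self.kind == "delta":
            if self.sigma is not None:
                raise ValueError("delta distribution takes no sigma")
        elif self.kind == "gaussian_on_sphere":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian_on_sphere requires sigma > 0")


@dataclass(frozen=True)
class Moments:
    """Raw axial moments ``m2 = <cos^2 theta>``, ``m4 = <cos^4 theta>``."""

    m2: float
    m4: float

    def validate(self, tol: float = _FEAS_TOL) -> None:
        """Raise :class:`FeasibilityError` naming the first violated bound."""
        if not (-tol <= self.m2 <= 1.0 + tol):
            raise FeasibilityError(f"m2={self.m2} outside [0, 1]")
        if not (-tol <= self.m4 <= 1.0 + tol):
            raise FeasibilityError(f"m4={self.m4} outside [0, 1]")
        if self.m4 > self.m2 + tol:
            raise FeasibilityError(f"m4={self.m4} exceeds m2={self.m2}")
        if self.m4 < self.m2 ** 2 - tol:
            raise FeasibilityError(
                f"m4={self.m4} below m2^2={self.m2 ** 2} (Jensen bound)"
            )

    @property
    def feasible(self) -> bool:
        try:
            self.validate()
        except FeasibilityError:
            return False
        return True


def _gaussian_density(theta: float, theta0: float, sigma: float) -> float:
    # reflect the gaussian at theta = 0 and theta = pi by summing images
    total = 0.0
    for n in range(-2, 3):
        for t0 in (theta0, -theta0):
            total += math.exp(-((theta - t0 - 2.0 * math.pi * n) ** 2)
                              / (2.0 * sigma ** 2))
    return total * math.sin(theta)


def moments_from_distribution(dist: AngleDistribution) -> Moments:
    """Compute ``<cos^2 theta>`` and ``<cos^4 theta>`` for a distribution.

    Delta distributions use the closed form; gaussians are integrated by
    adaptive quadrature with the ``sin(theta)`` solid-angle weight; mixtures
    are weight-averaged component-wise.
    """
    if dist.kind == "delta":
        c = math.cos(math.radians(dist.theta0))
        return Moments(m2=c * c, m4=c ** 4)
    if dist.kind == "mixture":
        m2 = m4 = 0.0
        for w, sub in dist.components:
            sub_m = moments_from_distribution(sub)
            m2 += w * sub_m.m2
            m4 += w * sub_m.m4
        return Moments(m2=m2, m4=m4)

    theta0 = math.radians(dist.theta0)
    sigma = math.radians(dist.sigma)

    def integrate(power: int) -> float:
        val, _ = quad(
            lambda t: math.cos(t) ** power * _gaussian_density(t, theta0, sigma),
            0.0, math.pi,
            epsabs=_QUAD_EPSABS, epsrel=1e-12, limit=400,
            points=[theta0] if sigma < 0.5 else None,
        )
        return val

    norm = integrate(0)
    return Moments(m2=integrate(2) / norm, m4=integrate(4) / norm)


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderParameterSet:
    """Legendre order parameters of a dipole population.

    ``p2`` lies in [-0.5, 1] (+1 all-parallel, -0.5 all-perpendicular);
    ``p4`` in [-3/7, 1].  ``p2d`` is the fast sub-nanosecond wobble order
    parameter, treated throughout as a supplied constant.
    """

    p2: float
    p4: float
    p2d: Optional[float] = None

    def moments(self) -> Moments:
        return moments_from_order_params(self)

    def validate(self, tol: float = _FEAS_TOL) -> None:
        self.moments().validate(tol)
        if self.p2d is not None and not (0.0 <= self.p2d <= 1.0):
            raise ValueError("p2d must lie in [0, 1]")


def order_params_from_moments(m: Moments) -> OrderParameterSet:
    """Legendre transform of feasible raw moments (``p2d`` left unset)."""
    m.validate()
    p2 = (3.0 * m.m2 - 1.0) / 2.0
    p4 = (35.0 * m.m4 - 30.0 * m.m2 + 3.0) / 8.0
    return OrderParameterSet(p2=p2, p4=p4)


def moments_from_order_params(ops: OrderParameterSet) -> Moments:
    """Inverse of :func:`order_params_from_moments` (no feasibility check)."""
    m2 = (2.0 * ops.p2 + 1.0) / 3.0
    m4 = (8.0 * ops.p4 + 30.0 * m2 - 3.0) / 35.0
    return Moments(m2=m2, m4=m4)


def mixture_p2(fractions: Sequence[float], p2s: Sequence[float]) -> float:
    """Population-weighted ``p2`` — observed ``p2`` of a dipole mixture.

    The observed order parameter is linear in the fraction of dipoles in
    each sub-population, so a mixture's ``p2`` is the weighted mean.
    """
    w = np.asarray(fractions, dtype=float)
    p = np.asarray(p2s, dtype=float)
    if w.shape != p.shape:
        raise ValueError("fractions and p2s must have equal length")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("fractions must be non-negative and sum to 1")
    if np.any(p < -0.5 - 1e-12) or np.any(p > 1.0 + 1e-12):
        raise ValueError("each p2 must lie in [-0.5, 1]")
    return float(np.dot(w, p))


def apply_attenuation(ops: OrderParameterSet, d2: float, d4: float) -> OrderParameterSet:
    """Attenuate order parameters by nested-disorder factors in [0, 1].

    Statistically independent nested disorders (e.g. myofibrillar
    misalignment on top of probe orientation) multiply order parameters:
    ``p2' = p2*d2``, ``p4' = p4*d4``.  The attenuated pair must remain
    feasible; if not, a :class:`FeasibilityError` is raised.
    """
    if not (0.0 <= d2 <= 1.0 and 0.0 <= d4 <= 1.0):
        raise ValueError("attenuation factors must lie in [0, 1]")
    out = OrderParameterSet(p2=ops.p2 * d2, p4=ops.p4 * d4, p2d=ops.p2d)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# forward model and inversion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarizedIntensitySet:
    """Four polarized fluorescence components (excitation, emission) =
    (par, par), (par, perp), (perp, par), (perp, perp) relative to the
    fiber axis, in arbitrary units, plus an overall brightness ``scale``."""

    i_pp: float
    i_pt: float
    i_tp: float
    i_tt: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("i_pp", "i_pt", "i_tp", "i_tt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def cross_asymmetry(self) -> float:
        """Relative |i_pt - i_tp| — zero under the static uniaxial model;
        deviation diagnoses noise or misalignment."""
        denom = 0.5 * (self.i_pt + self.i_tp)
        if denom == 0:
            return 0.0
        return abs(self.i_pt - self.i_tp) / denom


@dataclass(frozen=True)
class InversionResult:
    """Order parameters recovered from measured intensities."""

    ops: OrderParameterSet
    scale: float
    projected: bool          #: True if infeasible moments were projected
    cross_asymmetry: float   #: quality metric, 0 under the static model


def forward_intensities(ops: OrderParameterSet, scale: float) -> PolarizedIntensitySet:
    """Predict the four polarized components from order parameters.

    With ``m2, m4`` the raw moments,

    * ``i_pp = scale * m4``                      (= ``<cos^4 theta>``)
    * ``i_pt = i_tp = scale * (m2 - m4) / 2``    (= ``<cos^2 sin^2>/2``)
    * ``i_tt = scale * 3/8 * (1 - 2 m2 + m4)``   (= ``3/8 <sin^4 theta>``)
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    m = moments_from_order_params(ops)
    m.validate()
    i_pp = scale * m.m4
    i_x = scale * (m.m2 - m.m4) / 2.0
    i_tt = scale * 0.375 * (1.0 - 2.0 * m.m2 + m.m4)
    # clamp tiny negative round-off on the feasibility boundary
    return PolarizedIntensitySet(
        i_pp=max(i_pp, 0.0), i_pt=max(i_x, 0.0),
        i_tp=max(i_x, 0.0), i_tt=max(i_tt, 0.0), scale=scale,
    )


def project_moments(m: Moments) -> Moments:
    """Euclidean projection of (m2, m4) onto the feasible region
    ``{0 <= m2 <= 1, m2^2 <= m4 <= m2}``."""
    if m.feasible:
        return m
    x, y = m.m2, m.m4

    candidates = []

    # lower boundary: the parabola (t, t^2), t in [0, 1]
    res = minimize_scalar(
        lambda t: (t - x) ** 2 + (t * t - y) ** 2, bounds=(0.0, 1.0),
        method="bounded", options={"xatol": 1e-14},
    )
    candidates.append((res.fun, Moments(float(res.x), float(res.x) ** 2)))
    # upper boundary: the segment (t, t), t in [0, 1]
    t = min(max((x + y) / 2.0, 0.0), 1.0)
    candidates.append(((t - x) ** 2 + (t - y) ** 2, Moments(t, t)))
    # corners
    for cx, cy in ((0.0, 0.0), (1.0, 1.0)):
        candidates.append(((cx - x) ** 2 + (cy - y) ** 2, Moments(cx, cy)))

    return min(candidates, key=lambda c: c[0])[1]


def invert_intensities(obs: PolarizedIntensitySet) -> InversionResult:
    """Recover order parameters and brightness from measured intensities.

    ``i_pt`` and ``i_tp`` are averaged before the exact linear solve for
    ``(m2, m4, scale)``; their relative difference is reported as
    ``cross_asymmetry``.  Moments made infeasible by measurement noise are
    projected to the nearest feasible point and the result is flagged.
    """
    i_x = 0.5 * (obs.i_pt + obs.i_tp)
    total = obs.i_pp + 2.0 * i_x + obs.i_tt
    if total <= 0:
        raise ValueError("all intensity components are zero")

    # s*m4 = i_pp ; s*m2 = i_pp + 2 i_x ; s*(1 - 2 m2 + m4) = 8/3 i_tt
    scale = obs.i_pp + 4.0 * i_x + (8.0 / 3.0) * obs.i_tt
    m = Moments(m2=(obs.i_pp + 2.0 * i_x) / scale, m4=obs.i_pp / scale)

    projected = not m.feasible
    if projected:
        m = project_moments(m)
    ops = order_params_from_moments(m)
    return InversionResult(
        ops=ops, scale=scale, projected=projected,
        cross_asymmetry=obs.cross_asymmetry,
    )
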