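"""Free-Ca2+ solver for mixed Ca/Mg/EGTA/ATP bathing solutions.

Solves the coupled 1:1 binding equilibria Ca-EGTA, Mg-EGTA, Ca-ATP and
Mg-ATP under mass balance for total Ca, total EGTA and total ATP, with free
Mg2+ clamped at its target value (total Mg is an *output*).  Protonation
microstates are folded into user-supplied APPARENT association constants at
the stated pH / temperature / ionic strength; the shipped defaults
(:data:`DEFAULT_CONSTANTS`) are representative values for pH 7.1, 20 C,
0.2 M ionic strength and are defaults only — supply your own constants for
quantitative work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

__all__ = [
    "SolutionRecipe",
    "FreeCaResult",
    "DEFAULT_CONSTANTS",
    "free_ca_from_pca",
    "pca_from_free_ca",
    "solve_free_ca",
    "total_ca_for_target_pca",
]

#: Apparent 1:1 association constants (M^-1), pH 7.1, 20 C, I = 0.2 M.
#: Defaults only; not asserted against any external reference.
DEFAULT_CONSTANTS: Dict[str, float] = {
    "k_ca_egta": 4.0e6,
    "k_mg_egta": 40.0,
    "k_ca_atp": 5.0e3,
    "k_mg_atp": 1.0e4,
}

_RESIDUAL_TOL = 1e-12   # M, absolute tolerance on the total-Ca residual
_MAX_ITER = 200


@dataclass
class SolutionRecipe:
    """Composition of one bathing solution (all concentrations molar)."""

    total_ca: float = 0.0
    total_egta: float = 10e-3
    total_atp: float = 5e-3
    free_mg: float = 1e-3           # clamped free Mg2+ target
    k_ca_egta: float = DEFAULT_CONSTANTS["k_ca_egta"]
    k_mg_egta: float = DEFAULT_CONSTANTS["k_mg_egta"]
    k_ca_atp: float = DEFAULT_CONSTANTS["k_ca_atp"]
    k_mg_atp: float = DEFAULT_CONSTANTS["k_mg_atp"]
    ph: float = 7.1
    temperature_c: float = 20.0
    ionic_strength: float = 0.2

    def __post_init__(self) -> None:
        for name in ("total_ca", "total_egta", "total_atp", "free_mg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("k_ca_egta", "k_mg_egta", "k_ca_atp", "k_mg_atp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SolutionRecipe":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown recipe fields: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FreeCaResult:
    free_ca: float                  # M
    pca: float                      # -log10 free Ca; +inf when free Ca == 0
    species: Dict[str, float]       # molar concentration of every species
    residuals: Dict[str, float]     # conservation residuals (M)
    iterations: int


def free_ca_from_pca(pca: float) -> float:
    """Free [Ca2+] in molar for a pCa value: ``10**(-pca)``."""
    if not math.isfinite(pca):
        raise ValueError("pca must be finite")
    return 10.0 ** (-pca)


def pca_from_free_ca(free_ca: float) -> float:
    """pCa = -log10 of free [Ca2+] (M); +inf for zero free Ca."""
    if free_ca < 0:
        raise ValueError("free_ca must be non-negative")
    if free_ca == 0.0:
        return math.inf
    return -math.log10(free_ca)


def _free_buffers(recipe: SolutionRecipe, ca: float) -> tuple[float, float]:
    """Free EGTA and free ATP at given free Ca, with free Mg clamped."""
    mg = recipe.free_mg
    egta = recipe.total_egta / (1.0 + recipe.k_ca_egta * ca + recipe.k_mg_egta * mg)
    atp = recipe.total_atp / (1.0 + recipe.k_ca_atp * ca + recipe.k_mg_atp * mg)
    return egta, atp


def _total_ca_at(recipe: SolutionRecipe, ca: float) -> float:
    """Total Ca implied by a free-Ca value (explicit mass balance)."""
    egta, atp = _free_buffers(recipe, ca)
    return ca * (1.0 + recipe.k_ca_egta * egta + recipe.k_ca_atp * atp)


def _species_table(recipe: SolutionRecipe, ca: float) -> Dict[str, float]:
    egta, atp = _free_buffers(recipe, ca)
    mg = recipe.free_mg
    return {
        "ca_free": ca,
        "mg_free": mg,
        "egta_free": egta,
        "atp_free": atp,
        "ca_egta": recipe.k_ca_egta * ca * egta,
        "mg_egta": recipe.k_mg_egta * mg * egta,
        "ca_atp": recipe.k_ca_atp * ca * atp,
        "mg_atp": recipe.k_mg_atp * mg * atp,
    }


def solve_free_ca(recipe: SolutionRecipe) -> FreeCaResult:
    """Solve for free Ca2+ by monotone bisection on the mass-balance residual.

    The residual ``total_ca(ca_free) - recipe.total_ca`` is strictly
    increasing in ``ca_free``, so bisection on [0, total_ca] converges
    unconditionally; iteration stops when |residual| < 1e-12 M.
    """
    if recipe.total_ca == 0.0:
        species = _species_table(recipe, 0.0)
        return FreeCaResult(
            free_ca=0.0, pca=math.inf, species=species,
            residuals=_residuals(recipe, species), iterations=0,
        )

    lo, hi = 0.0, recipe.total_ca
    ca = 0.5 * (lo + hi)
    for it in range(1, _MAX_ITER + 1):
        resid = _total_ca_at(recipe, ca) - recipe.total_ca
        if abs(resid) < _RESIDUAL_TOL:
            break
        if resid > 0:
            hi = ca
        else:
            lo = ca
        ca = 0.5 * (lo + hi)
    else:
        raise RuntimeError(
            f"free-Ca bisection did not reach |residual| < {_RESIDUAL_TOL} M "
            f"in {_MAX_ITER} iterations"
        )

    species = _species_table(recipe, ca)
    if any(v < 0 for v in species.values()):
        raise RuntimeError("negative species concentration")
    return FreeCaResult(
        free_ca=ca, pca=pca_from_free_ca(ca), species=species,
        residuals=_residuals(recipe, species), iterations=it,
    )


def _residuals(recipe: SolutionRecipe, sp: Dict[str, float]) -> Dict[str, float]:
    return {
        "ca": sp["ca_free"] + sp["ca_egta"] + sp["ca_atp"] - recipe.total_ca,
        "egta": sp["egta_free"] + sp["ca_egta"] + sp["mg_egta"] - recipe.total_egta,
        "atp": sp["atp_free"] + sp["ca_atp"] + sp["mg_atp"] - recipe.total_atp,
    }


def total_ca_for_target_pca(
    recipe: SolutionRecipe, target_pca: float, max_total_ca: float = 0.1
) -> float:
    """Total Ca needed so the solved free Ca equals ``10**(-target_pca)``.

    With free Mg clamped the mass balance is explicit in the free->total
    direction, so the answer is evaluated directly; the forward solve of the
    returned total reproduces the target within the solver tolerance.
    """
    free = free_ca_from_pca(target_pca)
    total = _total_ca_at(recipe, free)
    if total > max_total_ca:
        raise ValueError(
            f"target pCa {target_pca} needs total Ca {total:.4g} M, "
            f"above the {max_total_ca} M bracket"
        )
    return total
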