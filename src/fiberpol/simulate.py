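"""Synthetic trabecula cohort generator.

Emulates the statistical structure of a paired length-dependent-activation
experiment: per-trabecula pCa titrations of force and of probe orientation
(``<P2>``) at two sarcomere lengths, optionally before/after force
inhibition, with Hill-shaped Ca dependence, SL-dependent myofibrillar
alignment attenuation, multiplicative measurement noise and
between-trabecula random offsets.  Every stage downstream (inversion,
fitting, summary statistics) is testable against the emitted ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import (
    BLEBBISTATIN_SERIES,
    LENGTH_SERIES,
    RLC_SERIES,
    ProbeConditionSummary,
)
from .hill import HillParameters, hill_eval, hill_fraction
from .orientation import OrderParameterSet, apply_attenuation, forward_intensities

__all__ = [
    "PCA_GRID",
    "CurveTruth",
    "ConditionEffectTable",
    "NoiseModel",
    "MeasurementRecord",
    "hill_from_anchors",
    "default_effect_table",
    "generate_trabecula",
    "generate_cohort",
]

#: default per-trabecula titration grid (pCa)
PCA_GRID: Tuple[float, ...] = (9.0, 6.6, 6.0, 5.8, 5.6, 5.5, 5.4, 5.2, 5.0, 4.5)

RECORD_COLUMNS = [
    "trabecula_id", "probe", "sl_um", "pca", "treatment",
    "i_pp", "i_pt", "i_tp", "i_tt", "force", "seed_provenance",
]


@dataclass(frozen=True)
class CurveTruth:
    """Generating Hill curve on the observed (post-attenuation) scale."""

    pca50: float
    n_h: float
    baseline: float
    amplitude: float

    def eval(self, pca) -> np.ndarray:
        return self.baseline + self.amplitude * hill_fraction(
            pca, self.pca50, self.n_h
        )

    def as_hill(self) -> HillParameters:
        return HillParameters(pca50=self.pca50, n_h=self.n_h,
                              baseline=self.baseline, amplitude=self.amplitude)


def hill_from_anchors(
    pca50: float, n_h: float,
    resp_relaxed: float, resp_active: float,
    pca_relaxed: float = 6.0, pca_active: float = 4.5,
) -> CurveTruth:
    """Hill curve through two anchor responses at fixed pCa50 and n_h.

    Solves baseline and amplitude so the curve passes exactly through
    (pca_relaxed, resp_relaxed) and (pca_active, resp_active).
    """
    f_lo = float(hill_fraction(pca_relaxed, pca50, n_h))
    f_hi = float(hill_fraction(pca_active, pca50, n_h))
    amplitude = (resp_active - resp_relaxed) / (f_hi - f_lo)
    baseline = resp_relaxed - amplitude * f_lo
    return CurveTruth(pca50=pca50, n_h=n_h, baseline=baseline,
                      amplitude=amplitude)


@dataclass
class ConditionEffectTable:
    """Generating truth per (probe, sl_um, treatment) condition.

    ``p2_curves`` and ``force_curves`` hold observed-scale Hill curves;
    ``alignment`` maps sarcomere length to the (d2, d4) disorder attenuation
    applied inside the optical forward model (larger, i.e. closer to 1, at
    the longer SL where myofibrils are better aligned).  ``p2d`` is carried
    as metadata; with ``apply_p2d=True`` it multiplies d2 as an extra
    attenuation factor.
    """

    p2_curves: Dict[Tuple[str, float, str], CurveTruth]
    force_curves: Dict[Tuple[str, float, str], CurveTruth]
    alignment: Dict[float, Tuple[float, float]] = field(
        default_factory=lambda: {1.9: (0.85, 0.65), 2.3: (0.90, 0.75)}
    )
    p2d: float = 0.85
    apply_p2d: bool = False

    def __post_init__(self) -> None:
        for sl, (d2, d4) in self.alignment.items():
            if not (0.0 <= d2 <= 1.0 and 0.0 <= d4 <= 1.0):
                raise ValueError(f"alignment factors for SL {sl} not in [0, 1]")
        if set(self.p2_curves) != set(self.force_curves):
            raise ValueError("p2_curves and force_curves must share keys")

    def conditions(self, probe: str) -> List[Tuple[float, str]]:
        return sorted(
            {(sl, trt) for (p, sl, trt) in self.p2_curves if p == probe}
        )

    def probes(self) -> List[str]:
        return sorted({p for (p, _, _) in self.p2_curves})

    def attenuation(self, sl: float) -> Tuple[float, float]:
        d2, d4 = self.alignment[sl]
        if self.apply_p2d:
            d2 = d2 * self.p2d
        return d2, d4


def default_effect_table(design: str = "length_series") -> ConditionEffectTable:
    """Effect table built from the shipped calibration summaries.

    design ``"length_series"``: TnC C- and E-helix probes, control, SL 1.9
    and 2.3.  ``"blebbistatin"``: same probes at SL 1.9 control plus
    blebbistatin at both SLs.  ``"rlc"``: myosin RLC probe, control, both
    SLs (``<P2>`` increases on activation).
    """
    series = {
        "length_series": LENGTH_SERIES,
        "blebbistatin": BLEBBISTATIN_SERIES,
        "rlc": RLC_SERIES,
    }.get(design)
    if series is None:
        raise ValueError(f"unknown design {design!r}")

    p2_curves, force_curves = {}, {}
    for key, summ in series.items():
        p2_curves[key] = hill_from_anchors(
            summ.p2_pca50, summ.p2_nh, summ.p2_at_pca6, summ.p2_at_pca45
        )
        f_sat = float(hill_fraction(4.5, summ.force_pca50, summ.force_nh))
        force_curves[key] = CurveTruth(
            pca50=summ.force_pca50, n_h=summ.force_nh,
            baseline=0.0, amplitude=summ.force_max / f_sat,
        )
    return ConditionEffectTable(p2_curves=p2_curves, force_curves=force_curves)


@dataclass
class NoiseModel:
    """Measurement and between-trabecula noise magnitudes.

    Defaults are calibrated so that cohort SEMs at n = 5-7 land near the
    published +/- values; they are not measured quantities.
    """

    intensity_cv: float = 0.02          # multiplicative, per component
    force_cv: float = 0.03
    pca50_sd: float = 0.05              # between-trabecula offset on pCa50
    baseline_p2_sd: float = 0.005       # between-trabecula offset on <P2> baseline

    def __post_init__(self) -> None:
        for name in ("intensity_cv", "force_cv", "pca50_sd", "baseline_p2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class MeasurementRecord:
    trabecula_id: str
    probe: str
    sl_um: float
    pca: float
    treatment: str
    i_pp: float
    i_pt: float
    i_tp: float
    i_tt: float
    force: float
    seed_provenance: str


def _p2_to_intensities(p2_obs: float, d2: float, d4: float, scale: float):
    """Map an observed ``<P2>`` to the four intensity components.

    The pre-attenuation population is taken as a delta function at the mean
    angle (the one-parameter ``<P4>`` closure: p4 computed from the theta
    solving p2 = P2(cos theta)); attenuation is then applied and the static
    forward model evaluated.
    """
    if d2 <= 0:
        raise ValueError("d2 must be positive to realize a nonzero <P2>")
    p2_pre = p2_obs / d2
    if not (-0.5 <= p2_pre <= 1.0):
        raise ValueError(
            f"observed p2 {p2_obs} with attenuation d2={d2} implies "
            f"pre-attenuation p2 {p2_pre} outside [-0.5, 1]"
        )
    c2 = (2.0 * p2_pre + 1.0) / 3.0         # cos^2 of the mean angle
    p4_pre = (35.0 * c2 * c2 - 30.0 * c2 + 3.0) / 8.0
    ops = apply_attenuation(
        OrderParameterSet(p2=p2_pre, p4=p4_pre), d2, d4
    )
    return forward_intensities(ops, scale)


def generate_trabecula(
    effects: ConditionEffectTable,
    noise: NoiseModel,
    seed,
    probe: str = "cTnC-C",
    trabecula_id: str = "T01",
    pca_grid: Sequence[float] = PCA_GRID,
    scale: float = 1000.0,
    provenance: Optional[str] = None,
) -> Tuple[List[MeasurementRecord], List[dict]]:
    """Simulate one trabecula over its full condition grid.

    Returns the measurement records and the realized per-condition ground
    truth (generating Hill parameters including this trabecula's random
    offsets, the expected anchor responses, and the attenuation factors).
    Fully deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if provenance is None:
        provenance = f"seed={seed}" if isinstance(seed, int) else "seed=derived"

    d_pca50 = rng.normal(0.0, noise.pca50_sd) if noise.pca50_sd else 0.0
    d_base = rng.normal(0.0, noise.baseline_p2_sd) if noise.baseline_p2_sd else 0.0

    records: List[MeasurementRecord] = []
    truth: List[dict] = []
    for sl, treatment in effects.conditions(probe):
        key = (probe, sl, treatment)
        p2_curve = effects.p2_curves[key]
        p2_curve = replace(p2_curve, pca50=p2_curve.pca50 + d_pca50,
                           baseline=p2_curve.baseline + d_base)
        f_curve = effects.force_curves[key]
        f_curve = replace(f_curve, pca50=f_curve.pca50 + d_pca50)
        d2, d4 = effects.attenuation(sl)

        for kind, curve in (("p2", p2_curve), ("force", f_curve)):
            r6 = float(curve.eval(6.0))
            r45 = float(curve.eval(4.5))
            truth.append({
                "trabecula_id": trabecula_id, "probe": probe, "sl_um": sl,
                "treatment": treatment, "response_kind": kind,
                "pca50": curve.pca50, "n_h": curve.n_h,
                "baseline": curve.baseline, "amplitude": curve.amplitude,
                "resp_at_pca6": r6, "resp_at_pca45": r45, "delta": r45 - r6,
                "d2": d2, "d4": d4,
                "p4_closure": "delta_at_mean_angle",
            })

        for pca in pca_grid:
            p2_true = float(p2_curve.eval(pca))
            force_true = float(f_curve.eval(pca))
            ints = _p2_to_intensities(p2_true, d2, d4, scale)
            comps = np.array([ints.i_pp, ints.i_pt, ints.i_tp, ints.i_tt])
            if noise.intensity_cv:
                comps = comps * (1.0 + noise.intensity_cv * rng.standard_normal(4))
                comps = np.clip(comps, 0.0, None)
            force = force_true
            if noise.force_cv:
                force = force * (1.0 + noise.force_cv * rng.standard_normal())
            records.append(MeasurementRecord(
                trabecula_id=trabecula_id, probe=probe, sl_um=sl,
                pca=float(pca), treatment=treatment,
                i_pp=float(comps[0]), i_pt=float(comps[1]),
                i_tp=float(comps[2]), i_tt=float(comps[3]),
                force=float(force), seed_provenance=provenance,
            ))
    return records, truth


def generate_cohort(
    n_trabeculae: int,
    effects: Optional[ConditionEffectTable] = None,
    noise: Optional[NoiseModel] = None,
    master_seed: int = 0,
    probes: Optional[Sequence[str]] = None,
    pca_grid: Sequence[float] = PCA_GRID,
    scale: float = 1000.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of ``n_trabeculae`` per probe.

    Per-trabecula seeds are spawned reproducibly from ``master_seed``.
    Returns ``(records, truth)`` frames; ``truth`` is the ground-truth
    sidecar used for parameter-recovery scoring.
    """
    if n_trabeculae < 2:
        raise ValueError("cohort needs n >= 2 trabeculae")
    effects = effects if effects is not None else default_effect_table()
    noise = noise if noise is not None else NoiseModel()
    probes = list(probes) if probes is not None else effects.probes()

    seed_seq = np.random.SeedSequence(master_seed)
    children = seed_seq.spawn(len(probes) * n_trabeculae)

    all_records: List[MeasurementRecord] = []
    all_truth: List[dict] = []
    idx = 0
    for probe in probes:
        for i in range(n_trabeculae):
            tid = f"{probe}-T{i + 1:02d}"
            recs, tru = generate_trabecula(
                effects, noise, children[idx], probe=probe,
                trabecula_id=tid, pca_grid=pca_grid, scale=scale,
                provenance=f"master_seed={master_seed}/spawn={idx}",
            )
            all_records.extend(recs)
            all_truth.extend(tru)
            idx += 1

    records = pd.DataFrame([r.__dict__ for r in all_records],
                           columns=RECORD_COLUMNS)
    truth = pd.DataFrame(all_truth)
    return records, truth
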