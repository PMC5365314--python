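"""Default calibration values for the synthetic cohort generator.

These are cohort-mean summary statistics (Hill parameters, ``<P2>`` plateau
anchors, maximal forces) for rat ventricular trabeculae carrying
bifunctional-rhodamine probes on the cTnC C helix, cTnC E helix or the
myosin RLC, at sarcomere lengths 1.9 and 2.3 um, with and without force
inhibition by 25 uM blebbistatin.  They are used (a) as generating truth
for synthetic cohorts and (b) as the reference inputs for the summary
arithmetic helpers.

Keys: probe in {"cTnC-C", "cTnC-E", "cRLC-BC"}; sl in {1.9, 2.3} um;
treatment in {"control", "blebbistatin"}.  Concentrations as pCa, forces in
mN/mm^2 (kPa), ``<P2>`` dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

__all__ = [
    "ProbeConditionSummary",
    "LENGTH_SERIES",
    "BLEBBISTATIN_SERIES",
    "RLC_SERIES",
    "sl_shift",
    "treatment_shift",
]

Key = Tuple[str, float, str]    # (probe, sl_um, treatment)


@dataclass(frozen=True)
class ProbeConditionSummary:
    """Cohort-mean summary for one (probe, SL, treatment) condition."""

    p2_pca50: float
    p2_nh: float
    p2_at_pca6: float        # relaxed-plateau anchor
    p2_at_pca45: float       # fully activated anchor
    force_pca50: float
    force_nh: float
    force_max: float         # mN/mm^2 at pCa 4.5
    n: int
    #: cohort-mean of the per-trabecula activation changes; because it is
    #: averaged per trabecula first, it can differ by ~0.003 from the
    #: difference of the anchor means.  None -> fall back to the anchors.
    delta_p2_mean: Optional[float] = None

    @property
    def delta_p2(self) -> float:
        """Signed activation change from the anchor means, pCa 6 -> 4.5."""
        return self.p2_at_pca45 - self.p2_at_pca6

    @property
    def delta_p2_reported(self) -> float:
        """Per-trabecula-averaged activation change when available."""
        if self.delta_p2_mean is not None:
            return self.delta_p2_mean
        return self.delta_p2


#: SL comparison series: both TnC probes, control solutions, both SLs.
LENGTH_SERIES: Dict[Key, ProbeConditionSummary] = {
    ("cTnC-C", 1.9, "control"): ProbeConditionSummary(
        p2_pca50=5.37, p2_nh=3.28, p2_at_pca6=0.108, p2_at_pca45=0.028,
        force_pca50=5.37, force_nh=4.03, force_max=22.7, n=5, delta_p2_mean=-0.081),
    ("cTnC-C", 2.3, "control"): ProbeConditionSummary(
        p2_pca50=5.48, p2_nh=3.42, p2_at_pca6=0.113, p2_at_pca45=0.036,
        force_pca50=5.50, force_nh=4.29, force_max=32.4, n=5, delta_p2_mean=-0.077),
    ("cTnC-E", 1.9, "control"): ProbeConditionSummary(
        p2_pca50=5.34, p2_nh=3.59, p2_at_pca6=0.283, p2_at_pca45=0.182,
        force_pca50=5.37, force_nh=4.12, force_max=23.2, n=5, delta_p2_mean=-0.101),
    ("cTnC-E", 2.3, "control"): ProbeConditionSummary(
        p2_pca50=5.45, p2_nh=3.24, p2_at_pca6=0.310, p2_at_pca45=0.208,
        force_pca50=5.49, force_nh=4.33, force_max=33.1, n=5, delta_p2_mean=-0.101),
}

#: Force-inhibition series.  Control rows are the pre-blebbistatin state of
#: the same trabeculae; treated force is suppressed to 1.5% of control.
BLEBBISTATIN_SERIES: Dict[Key, ProbeConditionSummary] = {
    ("cTnC-C", 1.9, "control"): ProbeConditionSummary(
        p2_pca50=5.40, p2_nh=3.29, p2_at_pca6=0.091, p2_at_pca45=0.009,
        force_pca50=5.39, force_nh=3.72, force_max=22.7, n=5, delta_p2_mean=-0.082),
    ("cTnC-C", 1.9, "blebbistatin"): ProbeConditionSummary(
        p2_pca50=5.32, p2_nh=2.74, p2_at_pca6=0.088, p2_at_pca45=0.016,
        force_pca50=5.39, force_nh=3.72, force_max=0.015 * 22.7, n=5, delta_p2_mean=-0.069),
    ("cTnC-C", 2.3, "blebbistatin"): ProbeConditionSummary(
        p2_pca50=5.41, p2_nh=2.49, p2_at_pca6=0.086, p2_at_pca45=0.024,
        force_pca50=5.50, force_nh=3.72, force_max=0.015 * 32.4, n=5, delta_p2_mean=-0.062),
    ("cTnC-E", 1.9, "control"): ProbeConditionSummary(
        p2_pca50=5.35, p2_nh=3.57, p2_at_pca6=0.276, p2_at_pca45=0.168,
        force_pca50=5.39, force_nh=4.23, force_max=23.2, n=7, delta_p2_mean=-0.098),
    ("cTnC-E", 1.9, "blebbistatin"): ProbeConditionSummary(
        p2_pca50=5.28, p2_nh=2.90, p2_at_pca6=0.282, p2_at_pca45=0.202,
        force_pca50=5.39, force_nh=4.23, force_max=0.015 * 23.2, n=7, delta_p2_mean=-0.080),
    ("cTnC-E", 2.3, "blebbistatin"): ProbeConditionSummary(
        p2_pca50=5.36, p2_nh=2.60, p2_at_pca6=0.305, p2_at_pca45=0.225,
        force_pca50=5.49, force_nh=4.23, force_max=0.015 * 33.1, n=7, delta_p2_mean=-0.080),
}

#: Myosin RLC probe: ``<P2>`` increases on activation.  No published anchor
#: values exist for this condition grid; these defaults encode only the
#: qualitative structure (positive activation change, SL-shifted pCa50).
RLC_SERIES: Dict[Key, ProbeConditionSummary] = {
    ("cRLC-BC", 1.9, "control"): ProbeConditionSummary(
        p2_pca50=5.40, p2_nh=3.3, p2_at_pca6=0.040, p2_at_pca45=0.095,
        force_pca50=5.38, force_nh=4.0, force_max=23.0, n=5),
    ("cRLC-BC", 2.3, "control"): ProbeConditionSummary(
        p2_pca50=5.51, p2_nh=3.3, p2_at_pca6=0.050, p2_at_pca45=0.110,
        force_pca50=5.50, force_nh=4.2, force_max=32.2, n=5),
}


def sl_shift(series: Dict[Key, ProbeConditionSummary], probe: str,
             attr: str, treatment: str = "control") -> float:
    """Long-SL minus short-SL difference of one summary attribute."""
    lo = getattr(series[(probe, 1.9, treatment)], attr)
    hi = getattr(series[(probe, 2.3, treatment)], attr)
    return hi - lo


def treatment_shift(series: Dict[Key, ProbeConditionSummary], probe: str,
                    attr: str, sl: float = 1.9,
                    treatment: str = "blebbistatin") -> float:
    """Treated minus control difference of one summary attribute at one SL."""
    ctrl = getattr(series[(probe, sl, "control")], attr)
    trt = getattr(series[(probe, sl, treatment)], attr)
    return trt - ctrl
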