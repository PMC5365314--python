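"""Pipeline stages tying the modules together: invert -> fit -> report."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .hill import TitrationCurve, delta_p2, fit_hill
from .orientation import PolarizedIntensitySet, invert_intensities
from .stats import build_summary_table

__all__ = ["invert_records", "fit_records", "run_pipeline"]

RECORD_REQUIRED = [
    "trabecula_id", "probe", "sl_um", "pca", "treatment",
    "i_pp", "i_pt", "i_tp", "i_tt",
]
FIT_GROUP = ["trabecula_id", "probe", "sl_um", "treatment"]


class SchemaError(ValueError):
    """A required column is missing or malformed."""


def _require_columns(df: pd.DataFrame, required, where: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing required column(s) {missing}")


def invert_records(records: pd.DataFrame) -> pd.DataFrame:
    """Invert the four intensity columns row-wise to order parameters.

    Adds columns ``p2, p4, scale, feasibility_flag, cross_asymmetry``.
    Raises :class:`SchemaError` with row context on malformed input.
    """
    _require_columns(records, RECORD_REQUIRED, "intensity table")
    out = records.copy()
    p2s, p4s, scales, flags, asyms = [], [], [], [], []
    for idx, row in records.iterrows():
        try:
            obs = PolarizedIntensitySet(
                i_pp=float(row["i_pp"]), i_pt=float(row["i_pt"]),
                i_tp=float(row["i_tp"]), i_tt=float(row["i_tt"]),
            )
            res = invert_intensities(obs)
        except ValueError as exc:
            raise SchemaError(f"intensity table row {idx}: {exc}") from exc
        p2s.append(res.ops.p2)
        p4s.append(res.ops.p4)
        scales.append(res.scale)
        flags.append(res.projected)
        asyms.append(res.cross_asymmetry)
    out["p2"] = p2s
    out["p4"] = p4s
    out["scale"] = scales
    out["feasibility_flag"] = flags
    out["cross_asymmetry"] = asyms
    return out


def fit_records(
    inverted: pd.DataFrame,
    normalize_force: bool = False,
) -> pd.DataFrame:
    """Per-trabecula Hill fits of ``p2`` and (when present) ``force``.

    One output row per (trabecula, probe, sl_um, treatment, response_kind)
    with the fitted Hill parameters, standard errors, the responses at the
    pCa 6 / 4.5 anchors, and the signed activation change ``delta``.
    Force curves are fit with the baseline fixed at zero.
    """
    _require_columns(inverted, FIT_GROUP + ["pca", "p2"], "order-parameter table")
    has_force = "force" in inverted.columns

    rows = []
    for keys, grp in inverted.groupby(FIT_GROUP, sort=True):
        tid, probe, sl, treatment = keys
        kinds = [("p2", grp["p2"].to_numpy(), None)]
        if has_force:
            kinds.append(("force", grp["force"].to_numpy(), 0.0))
        for kind, resp, fix_baseline in kinds:
            curve = TitrationCurve(
                pca=grp["pca"].to_numpy(), response=resp,
                response_kind=kind, probe=probe, sl_um=sl,
                treatment=treatment, trabecula_id=tid,
            )
            params = fit_hill(
                curve, fix_baseline=fix_baseline,
                normalize=(normalize_force and kind == "force"),
            )
            try:
                delta = delta_p2(curve)
                r6 = float(curve.response[np.isclose(curve.pca, 6.0)].mean())
                r45 = float(curve.response[np.isclose(curve.pca, 4.5)].mean())
            except ValueError:
                delta, r6, r45 = np.nan, np.nan, np.nan
            rows.append({
                "trabecula_id": tid, "probe": probe, "sl_um": sl,
                "treatment": treatment, "response_kind": kind,
                "pca50": params.pca50, "n_h": params.n_h,
                "baseline": params.baseline, "amplitude": params.amplitude,
                "se_pca50": params.se_pca50, "se_nh": params.se_nh,
                "resp_at_pca6": r6, "resp_at_pca45": r45, "delta": delta,
                "converged": params.converged, "degenerate": params.degenerate,
            })
    return pd.DataFrame(rows)


def run_pipeline(
    records: pd.DataFrame,
    layout: str = "table1",
    alpha: float = 0.05,
    normalize_force: bool = False,
) -> dict:
    """Execute invert -> fit -> summarize on an intensity table.

    Returns ``{"inverted": ..., "fits": ..., "summary": ...}`` frames.
    """
    inverted = invert_records(records)
    fits = fit_records(inverted, normalize_force=normalize_force)
    summary = build_summary_table(fits, layout=layout, alpha=alpha)
    return {"inverted": inverted, "fits": fits, "summary": summary}
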