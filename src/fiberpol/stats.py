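"""Paired-design comparisons and assembly of cohort summary tables.

Comparisons are paired throughout (same trabecula measured at both
sarcomere lengths, or before/after force inhibition), assessed with a
classical two-tailed paired t-test.  No multiple-testing correction is
applied: each significance flag is a single alpha = 0.05 test, and the
rendered tables say so in a footer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "PairedTResult",
    "SummaryCell",
    "paired_t",
    "percent_change",
    "build_summary_table",
    "render_text_table",
]

ALPHA_DEFAULT = 0.05

# row order mirrors the published-style summary layout
_FORCE_QUANTITIES = ["force_max", "pca50", "n_h"]
_P2_QUANTITIES = ["pca50", "n_h", "at_pca6", "at_pca45", "delta_p2"]


@dataclass
class PairedSample:
    """Matched measurement vectors ``a`` and ``b`` keyed by subject ids."""

    ids: Sequence[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.ids) == self.a.size == self.b.size):
            raise ValueError("ids, a and b must have equal length")
        if self.a.size < 2:
            raise ValueError("paired sample needs n >= 2")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float                  # two-tailed
    mean_diff: float          # mean of b - a
    sem_diff: float
    n: int
    degenerate: bool = False  # zero variance of differences


def paired_t(sample: PairedSample) -> PairedTResult:
    """Two-tailed paired t-test on the differences ``b - a``.

    Zero-variance differences never raise: identical pairs give t = 0,
    p = 1; constant non-zero differences are flagged degenerate with p at
    the machine floor.
    """
    d = sample.b - sample.a
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    sem = sd / np.sqrt(n)

    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=0.0, p=1.0, mean_diff=0.0, sem_diff=0.0,
                                 n=n, degenerate=True)
        tiny = float(np.finfo(float).tiny)
        return PairedTResult(t=float(np.copysign(np.inf, mean)), p=tiny,
                             mean_diff=mean, sem_diff=0.0, n=n, degenerate=True)

    t = mean / sem
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return PairedTResult(t=float(t), p=p, mean_diff=mean, sem_diff=float(sem),
                         n=n, degenerate=False)


def percent_change(before: float, after: float) -> float:
    """Signed percent change ``100 * (after - before) / before``."""
    if before == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (after - before) / before


@dataclass
class SummaryCell:
    mean: float
    sem: float
    n: int
    flags: frozenset = frozenset()       # subset of {"star", "hash"}
    note: str = ""

    def __post_init__(self) -> None:
        if self.n >= 2 and self.sem < 0:
            raise ValueError("sem must be non-negative")


def _mean_sem(values: np.ndarray) -> Tuple[float, float, int]:
    n = values.size
    mean = float(values.mean()) if n else float("nan")
    if n >= 2:
        # identical values must give exactly 0, not rounding dust
        sem = 0.0 if np.ptp(values) == 0 else float(
            values.std(ddof=1) / np.sqrt(n))
    else:
        sem = float("nan")
    return mean, sem, n


def _quantity_columns(kind: str) -> List[str]:
    return _FORCE_QUANTITIES if kind == "force" else _P2_QUANTITIES


def _extract(records: pd.DataFrame, kind: str, quantity: str,
             **selector) -> pd.Series:
    """Per-trabecula values of one summary quantity, indexed by trabecula."""
    df = records[records["response_kind"] == kind]
    for col, val in selector.items():
        if col == "sl_um":
            df = df[np.isclose(df[col].astype(float), val)]
        else:
            df = df[df[col] == val]
    column = {
        "pca50": "pca50", "n_h": "n_h",
        "force_max": "resp_at_pca45",
        "at_pca6": "resp_at_pca6", "at_pca45": "resp_at_pca45",
        "delta_p2": "delta",
    }[quantity]
    return df.set_index("trabecula_id")[column].astype(float)


def _paired_flag(a: pd.Series, b: pd.Series, alpha: float) -> Tuple[bool, int, str]:
    """Run a paired t on the trabeculae common to both series."""
    common = sorted(set(a.index) & set(b.index))
    if len(common) < 2:
        return False, len(common), "insufficient pairs"
    res = paired_t(PairedSample(ids=common,
                                a=a.loc[common].to_numpy(),
                                b=b.loc[common].to_numpy()))
    if res.degenerate:
        return False, len(common), "degenerate (zero variance)"
    return res.p < alpha, len(common), ""


def build_summary_table(
    records: pd.DataFrame,
    layout: str = "table1",
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Assemble a cohort summary grid from a per-trabecula fit report.

    ``records`` is a fit-report frame with one row per (trabecula, probe,
    sl_um, treatment, response_kind) carrying columns ``pca50, n_h,
    resp_at_pca6, resp_at_pca45, delta``.

    layout ``"table1"``: per probe, control condition at both sarcomere
    lengths; a ``star`` flag on the long-SL cell marks p < alpha in the
    paired SL comparison.

    layout ``"table2"``: per probe, columns (SL 1.9 control, SL 1.9
    treated, SL 2.3 treated); ``star`` marks the treatment effect at SL 1.9
    and ``hash`` the SL effect under treatment.

    Returns a tidy frame with one row per (probe, response_kind, quantity,
    condition) and columns mean, sem, n, star, hash, note.
    """
    if layout not in ("table1", "table2"):
        raise ValueError("layout must be 'table1' or 'table2'")
    required = {"trabecula_id", "probe", "sl_um", "treatment", "response_kind",
                "pca50", "n_h", "resp_at_pca6", "resp_at_pca45", "delta"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"fit report missing columns: {sorted(missing)}")

    treatments = sorted(set(records["treatment"]))
    treated = next((t for t in treatments if t != "control"), None)
    if layout == "table1":
        conditions = [(1.9, "control"), (2.3, "control")]
        comparisons = [("star", 0, 1)]       # flag lands on the second member
    else:
        if treated is None:
            raise ValueError("table2 layout needs a non-control treatment")
        conditions = [(1.9, "control"), (1.9, treated), (2.3, treated)]
        comparisons = [("star", 0, 1), ("hash", 1, 2)]

    rows = []
    for probe in sorted(set(records["probe"])):
        kinds = sorted(set(records.loc[records["probe"] == probe,
                                       "response_kind"]))
        for kind in kinds:
            for quantity in _quantity_columns(kind):
                series = {}
                for sl, treatment in conditions:
                    series[(sl, treatment)] = _extract(
                        records, kind, quantity,
                        probe=probe, sl_um=sl, treatment=treatment,
                    )
                flags: Dict[Tuple[float, str], set] = {c: set() for c in conditions}
                notes: Dict[Tuple[float, str], str] = {c: "" for c in conditions}
                for flag_name, ia, ib in comparisons:
                    ca, cb = conditions[ia], conditions[ib]
                    if series[ca].empty or series[cb].empty:
                        continue
                    sig, npairs, note = _paired_flag(series[ca], series[cb], alpha)
                    if sig:
                        flags[cb].add(flag_name)
                    if note:
                        notes[cb] = note
                for sl, treatment in conditions:
                    vals = series[(sl, treatment)].to_numpy()
                    mean, sem, n = _mean_sem(vals)
                    fl = flags[(sl, treatment)]
                    rows.append({
                        "probe": probe, "response_kind": kind,
                        "quantity": quantity, "sl_um": sl,
                        "treatment": treatment,
                        "mean": mean, "sem": sem, "n": n,
                        "star": "star" in fl, "hash": "hash" in fl,
                        "note": notes[(sl, treatment)],
                    })
    return pd.DataFrame(rows)


def render_text_table(summary: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> str:
    """Aligned plain-text rendering of a summary frame."""
    lines = []
    for (probe, kind), block in summary.groupby(["probe", "response_kind"],
                                                sort=True):
        lines.append(f"{probe} — {kind}")
        for quantity, sub in block.groupby("quantity", sort=False):
            cells = []
            for _, row in sub.iterrows():
                marks = ("*" if row["star"] else "") + ("#" if row["hash"] else "")
                cells.append(
                    f"SL {row['sl_um']:.1f} {row['treatment']}: "
                    f"{row['mean']:.3f} ± {row['sem']:.3f}{marks} (n={row['n']})"
                )
            lines.append(f"  {quantity:<10s} " + " | ".join(cells))
        lines.append("")
    lines.append(
        f"flags: * / # mark p < {alpha:g} in the paired comparisons; "
        "no multiple-testing correction applied"
    )
    return "\n".join(lines)
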