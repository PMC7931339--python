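"""Relative qPCR quantification by the 2^-ddCq method.

Each sample's target Cq is normalized against the geometric mean of its
reference genes; on the Cq (log2) scale the geometric mean of linear
quantities is simply the arithmetic mean of the reference Cq values, so
dCq = Cq(target) - mean(Cq(refs)).  Relative expression is calibrated to the
female control (Con-F) cell: rel% = 100 * 2^(-dCq) / mean(2^(-dCq) over
calibrator samples).  Calibrating against the mean *linear* quantity (not
the mean dCq) is what pins the calibrator-cell mean at exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RelExpression", "delta_cq", "relative_expression", "cell_summary"]

CELLS = ("Con-F", "Con-M", "N3-F", "N3-M")


@dataclass
class RelExpression:
    sample_id: str
    target_id: str
    delta_cq: float
    rel_pct: float


def delta_cq(cq_target: float, cq_refs: Sequence[float]) -> float:
    """dCq against the reference-gene geometric mean (arithmetic mean of Cq)."""
    refs = np.asarray(cq_refs, dtype=float)
    if refs.size == 0:
        raise ValueError("at least one reference gene Cq is required")
    return float(cq_target - refs.mean())


def relative_expression(
    records: pd.DataFrame, calibrator: str = "Con-F"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2^-ddCq relative expression calibrated to a group-sex cell.

    ``records`` is long-format with columns sample_id, group, sex, target_id,
    cq_target, and one or more ``cq_ref_*`` columns.  Returns per-sample
    relative expression (%) and a per-cell mean +/- SD summary table.
    """
    required = {"sample_id", "group", "sex", "target_id", "cq_target"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    ref_cols = [c for c in records.columns if c.startswith("cq_ref")]
    if not ref_cols:
        raise ValueError("records must have at least one cq_ref_* column")

    df = records.copy()
    df["cell"] = df["group"].astype(str) + "-" + df["sex"].astype(str)
    df["delta_cq"] = df["cq_target"] - df[ref_cols].mean(axis=1)

    rows = []
    for target, sub in df.groupby("target_id", sort=False):
        cal = sub.loc[sub["cell"] == calibrator, "delta_cq"]
        if cal.empty:
            raise ValueError(f"calibrator cell {calibrator!r} empty for {target!r}")
        # calibrate against the mean *linear* quantity of the calibrator cell
        # so that the calibrator-cell mean relative expression is exactly 100%
        cal_linear = float(np.mean(2.0 ** (-cal)))
        rel = 2.0 ** (-sub["delta_cq"]) / cal_linear * 100.0
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sub["sample_id"],
                    "target_id": target,
                    "cell": sub["cell"],
                    "delta_cq": sub["delta_cq"],
                    "rel_pct": rel,
                }
            )
        )
    result = pd.concat(rows, ignore_index=True)
    return result, cell_summary(result)


def cell_summary(rel: pd.DataFrame) -> pd.DataFrame:
    """Mean relative expression % +/- SD per target and group-sex cell."""
    grp = rel.groupby(["target_id", "cell"])["rel_pct"]
    out = grp.agg(n="size", mean_rel_pct="mean", sd_rel_pct=lambda s: s.std(ddof=1))
    return out.reset_index()
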