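"""Pooled qPCR-array microRNA screening.

The screening design is one pooled sample per treatment group run on a
two-plate low-density qPCR array.  With a single pool per group there are no
replicates, so differential calls cannot come from a variance-based test.
Instead the screen works on the MA representation of the two pools:

* ``M``  — per-assay log2 fold change between the groups.  Because qPCR
  expression is proportional to ``2**-Cq``, we define ``M = Cq(Con) - Cq(N3)``
  so that positive M means *higher* expression in the intervention (N3) pool.
* ``A``  — mean Cq of the two pools, the abundance axis.

Intensity-dependent bias in M is removed with a cyclic-loess pass per plate
(with exactly two samples the cyclic procedure reduces to repeatedly fitting
and subtracting one loess curve of M on A).  Differential microRNAs are then
flagged with an adaptive cutoff: quadratic quantile-regression curves at the
0.05 and 0.95 quantiles of normalized M as a function of A; assays strictly
outside the envelope are called down/up.  Assays detected in exactly one
group are classified as group-unique and counted as differential.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.regression.quantile_regression import QuantReg

GROUPS = ("Con", "N3")
PLATES = ("A", "B")

__all__ = [
    "CqMatrix",
    "ScreenResult",
    "VennSummary",
    "FitError",
    "read_cq_table",
    "write_cq_table",
    "detect_calls",
    "compute_MA",
    "cyclic_loess_normalize",
    "adaptive_cutoff",
    "classify_and_summarize",
    "venn_from_counts",
    "round_half_up",
    "write_screen_results",
    "ma_plot",
]


class FitError(RuntimeError):
    """A normalization or quantile fit failed; message carries diagnostics."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CqMatrix:
    """Long-format Cq table: one row per (assay, group) well.

    ``data`` columns: assay_id (str), plate ('A'/'B'), group ('Con'/'N3'),
    cq (float, NaN when undetermined), undetermined (bool).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"assay_id", "plate", "group", "cq", "undetermined"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"CqMatrix missing columns: {sorted(missing)}")
        dup = df.duplicated(subset=["assay_id", "group"])
        if dup.any():
            rows = df.loc[dup, ["assay_id", "group"]].iloc[0]
            raise ValueError(
                f"duplicate (assay_id, group) pair: ({rows.assay_id!r}, {rows.group!r})"
            )
        plates_per_assay = df.groupby("assay_id")["plate"].nunique()
        bad = plates_per_assay[plates_per_assay > 1]
        if len(bad):
            raise ValueError(f"assay on more than one plate: {bad.index[0]!r}")
        ok = df["undetermined"] | np.isfinite(df["cq"])
        if not ok.all():
            raise ValueError("non-finite Cq in rows not flagged undetermined")
        if (~df["undetermined"] & (df["cq"] <= 0)).any():
            raise ValueError("Cq values must be positive")

    @property
    def assay_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["assay_id"]))

    def pivot(self) -> pd.DataFrame:
        """Wide per-assay frame: plate, cq_Con, cq_N3, undet_Con, undet_N3."""
        df = self.data
        wide = df.pivot(index="assay_id", columns="group", values="cq")
        undet = df.pivot(index="assay_id", columns="group", values="undetermined")
        plate = df.groupby("assay_id")["plate"].first()
        out = pd.DataFrame(index=wide.index)
        for g in GROUPS:
            out[f"cq_{g}"] = wide[g] if g in wide else np.nan
            # a missing well counts as undetermined for that group
            out[f"undet_{g}"] = (
                undet[g].fillna(True).astype(bool) if g in undet else True
            )
        out["plate"] = plate
        return out.loc[self.assay_ids]


@dataclass
class ScreenResult:
    """Per-assay screening outcome (one row of the differential table)."""

    assay_id: str
    detected_con: bool
    detected_n3: bool
    M: float  # log2 FC in cycles-equivalent units (NaN unless both detected)
    A: float  # mean Cq
    M_norm: float
    q_low: float
    q_high: float
    call: str  # up / down / unchanged / n3_only / con_only / undetected
    signed_fc: float
    median_cq: float


@dataclass
class VennSummary:
    """Detection / differential set arithmetic for the whole screen."""

    n_screened: int
    n_det_con: int
    n_det_n3: int
    n_common: int
    n_union: int
    n_unique_con: int
    n_unique_n3: int
    n_diff_common: int
    n_up: int
    n_down: int
    n_diff_total: int
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_union != self.n_det_con + self.n_det_n3 - self.n_common:
            raise ValueError("inclusion-exclusion violated")
        if self.n_diff_common != self.n_up + self.n_down:
            raise ValueError("n_diff_common must equal n_up + n_down")
        if self.n_diff_total != self.n_unique_con + self.n_unique_n3 + self.n_diff_common:
            raise ValueError("differential decomposition violated")
        counts = [
            self.n_det_con, self.n_det_n3, self.n_common, self.n_union,
            self.n_unique_con, self.n_unique_n3, self.n_diff_common,
            self.n_up, self.n_down, self.n_diff_total,
        ]
        if any(c < 0 or c > self.n_screened for c in counts):
            raise ValueError("counts must lie in [0, n_screened]")
        if not self.percentages:
            pct = lambda c: round_half_up(100.0 * c / self.n_screened, 1)
            self.percentages = {
                "det_con": pct(self.n_det_con),
                "det_n3": pct(self.n_det_n3),
                "common": pct(self.n_common),
                "union": pct(self.n_union),
                "diff_common": pct(self.n_diff_common),
                "diff_total": pct(self.n_diff_total),
            }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def venn_from_counts(
    n_screened: int,
    n_det_con: int,
    n_det_n3: int,
    n_common: int,
    *,
    n_up: int = 0,
    n_down: int = 0,
    n_unique_con_diff: int | None = None,
    n_unique_n3_diff: int | None = None,
) -> VennSummary:
    """Build a VennSummary directly from detection counts.

    Group-unique assays all count as differential; ``n_unique_*_diff``
    overrides that when only a subset was called.
    """
    uc = n_det_con - n_common if n_unique_con_diff is None else n_unique_con_diff
    un = n_det_n3 - n_common if n_unique_n3_diff is None else n_unique_n3_diff
    return VennSummary(
        n_screened=n_screened,
        n_det_con=n_det_con,
        n_det_n3=n_det_n3,
        n_common=n_common,
        n_union=n_det_con + n_det_n3 - n_common,
        n_unique_con=uc,
        n_unique_n3=un,
        n_diff_common=n_up + n_down,
        n_up=n_up,
        n_down=n_down,
        n_diff_total=uc + un + n_up + n_down,
    )


# ---------------------------------------------------------------------------
# IO


def read_cq_table(path: str | Path, undetermined_token: str = "Undetermined") -> CqMatrix:
    """Read a delimited Cq table with columns assay_id, plate, group, cq.

    The delimiter is sniffed (TSV or CSV).  Rows whose cq field equals
    ``undetermined_token`` are flagged undetermined; any other non-numeric
    cq raises a parse error naming the row.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = ["assay_id", "plate", "group", "cq"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    raw = df["cq"].astype(str).str.strip()
    undet = raw == undetermined_token
    cq = pd.to_numeric(raw.where(~undet), errors="coerce")
    bad = ~undet & cq.isna()
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: row {i + 2}: cannot parse cq value {raw.iloc[i]!r} "
            f"(not numeric and not {undetermined_token!r})"
        )
    out = pd.DataFrame(
        {
            "assay_id": df["assay_id"].astype(str),
            "plate": df["plate"].astype(str),
            "group": df["group"].astype(str),
            "cq": cq.astype(float),
            "undetermined": undet.to_numpy(),
        }
    )
    return CqMatrix(out)


def write_cq_table(
    cq: CqMatrix, path: str | Path, undetermined_token: str = "Undetermined"
) -> None:
    """Write a CqMatrix back to TSV, round-tripping values bit-exactly."""
    df = cq.data.copy()
    text = df["cq"].map(lambda v: repr(float(v)) if np.isfinite(v) else "")
    text = text.where(~df["undetermined"], undetermined_token)
    out = df[["assay_id", "plate", "group"]].copy()
    out["cq"] = text
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Screening statistics


def detect_calls(cq: CqMatrix, cq_max: float = 40.0) -> pd.DataFrame:
    """Per-assay detection per group: present, not undetermined, Cq < cq_max."""
    if cq_max <= 0:
        raise ValueError("cq_max must be positive")
    wide = cq.pivot()
    out = pd.DataFrame(index=wide.index)
    for g in GROUPS:
        out[f"detected_{g.lower()}"] = (
            ~wide[f"undet_{g}"] & np.isfinite(wide[f"cq_{g}"]) & (wide[f"cq_{g}"] < cq_max)
        )
    out["plate"] = wide["plate"]
    return out


def _signed_fc(m: float) -> float:
    """Fold-change encoding where down-regulation prints as a negative fold."""
    return 2.0 ** m if m >= 0 else -(2.0 ** (-m))


def compute_MA(cq_con: float, cq_n3: float) -> tuple[float, float, float]:
    """M/A statistics for one assay detected in both pools.

    M = Cq(Con) - Cq(N3): positive M means higher expression in N3 because
    expression scales as 2**-Cq.  A is the mean Cq.  signed_fc encodes
    2**M for M >= 0 and -2**(-M) otherwise.
    """
    if not (np.isfinite(cq_con) and np.isfinite(cq_n3)):
        raise ValueError("compute_MA requires both groups detected (finite Cq)")
    m = cq_con - cq_n3
    a = 0.5 * (cq_con + cq_n3)
    return m, a, _signed_fc(m)


MIN_POINTS_PER_PLATE = 10


def _spline_basis(a: np.ndarray, span: float) -> np.ndarray:
    """Low-rank natural-cubic-spline design for the M-on-A trend.

    The smoothing window maps to flexibility: interior knots are placed at
    quantiles of A, roughly 2/span of them, so a smaller span yields a more
    local fit.  Natural (linear-beyond-boundary) basis keeps the curve tame
    at the Cq extremes where points are sparse.
    """
    n_knots = max(1, int(round(2.0 / span)))
    probs = np.linspace(0, 1, n_knots + 2)
    knots = np.quantile(a, probs)
    knots = np.unique(knots)
    if len(knots) < 3:  # nearly constant A: fall back to a line
        return np.column_stack([np.ones_like(a), a])
    # natural cubic spline truncated-power basis (Hastie et al. convention)
    k = knots
    K = len(k)

    def d(j: int) -> np.ndarray:
        return (
            np.clip(a - k[j], 0, None) ** 3 - np.clip(a - k[K - 1], 0, None) ** 3
        ) / (k[K - 1] - k[j])

    cols = [np.ones_like(a), a]
    dK2 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK2)
    return np.column_stack(cols)


def cyclic_loess_normalize(
    M: Sequence[float],
    A: Sequence[float],
    plate: Sequence[str],
    span: float = 0.7,
    iterations: int = 1,
) -> np.ndarray:
    """Remove the intensity-dependent trend of M on A, separately per plate.

    With one pooled sample per group the cyclic procedure reduces to a
    single M-on-A trend fit per plate, which is subtracted from M.  The
    trend is fitted by least squares on a low-rank natural-spline basis (a
    linear projection), so the normalization is exactly idempotent:
    re-normalizing already-normalized values is a no-op to machine
    precision.  ``span`` controls smoothness via the number of interior
    knots (~2/span).  Undefined M (NaN) passes through untouched.  Plates
    with fewer than MIN_POINTS_PER_PLATE defined points are median-centered
    instead, with a warning.
    """
    M = np.asarray(M, dtype=float).copy()
    A = np.asarray(A, dtype=float)
    plate = np.asarray(plate)
    if not (len(M) == len(A) == len(plate)):
        raise ValueError("M, A and plate must have the same length")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    for p in np.unique(plate):
        sel = (plate == p) & np.isfinite(M) & np.isfinite(A)
        n = int(sel.sum())
        if n == 0:
            continue
        if n < MIN_POINTS_PER_PLATE:
            warnings.warn(
                f"plate {p!r}: only {n} points, median-centering instead of trend fit",
                stacklevel=2,
            )
            M[sel] -= np.median(M[sel])
            continue
        a, m = A[sel], M[sel]
        X = _spline_basis(a, span)
        for _ in range(iterations):  # extra passes are no-ops (projection)
            beta, *_ = np.linalg.lstsq(X, m, rcond=None)
            m = m - X @ beta
        M[sel] = m
    return M


def _poly_design(a: np.ndarray, degree: int, center: float, scale: float) -> np.ndarray:
    z = (a - center) / scale
    return np.column_stack([z ** k for k in range(degree + 1)])


def adaptive_cutoff(
    M_norm: Sequence[float],
    A: Sequence[float],
    taus: tuple[float, float] = (0.05, 0.95),
    degree: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quantile-regression envelope of M_norm on A and outside-envelope flags.

    For each tau a degree-``degree`` polynomial in A minimizing the pinball
    loss is fitted; points strictly below the low curve are flagged "below",
    strictly above the high curve "above", everything else (ties included)
    "inside".  Returns (q_low, q_high, flags) aligned to the input; entries
    with undefined M_norm get NaN curves and flag "undefined".
    """
    M_norm = np.asarray(M_norm, dtype=float)
    A = np.asarray(A, dtype=float)
    ok = np.isfinite(M_norm) & np.isfinite(A)
    n = int(ok.sum())
    if n < 10:
        raise ValueError(f"adaptive_cutoff needs >= 10 defined points, got {n}")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    a, m = A[ok], M_norm[ok]
    center, scale = float(a.mean()), float(a.std() or 1.0)
    X = _poly_design(a, degree, center, scale)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError(
            f"collinear design for quantile fit: rank {np.linalg.matrix_rank(X)} "
            f"< {X.shape[1]} columns (A values may be constant)"
        )
    curves = []
    for tau in taus:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = QuantReg(m, X).fit(q=tau, max_iter=5000)
            except Exception as exc:  # pragma: no cover - solver failure path
                raise FitError(f"quantile fit failed at tau={tau}: {exc}") from exc
        curves.append(X @ res.params)
    q_low_fit, q_high_fit = curves[0], curves[1]
    q_low = np.full(len(M_norm), np.nan)
    q_high = np.full(len(M_norm), np.nan)
    q_low[ok], q_high[ok] = q_low_fit, q_high_fit
    flags = np.full(len(M_norm), "undefined", dtype=object)
    flags[ok] = "inside"
    flags[ok & (M_norm < q_low)] = "below"
    flags[ok & (M_norm > q_high)] = "above"
    return q_low, q_high, flags


def classify_and_summarize(
    cq: CqMatrix,
    cq_max: float = 40.0,
    span: float = 0.7,
    taus: tuple[float, float] = (0.05, 0.95),
    degree: int = 2,
    n_screened: int | None = None,
) -> tuple[list[ScreenResult], VennSummary]:
    """Run the full screen: detect, MA, loess-normalize, flag, summarize."""
    wide = cq.pivot()
    det = detect_calls(cq, cq_max=cq_max)
    cq_con = wide["cq_Con"].to_numpy()
    cq_n3 = wide["cq_N3"].to_numpy()
    dcon = det["detected_con"].to_numpy()
    dn3 = det["detected_n3"].to_numpy()
    both = dcon & dn3

    M = np.where(both, cq_con - cq_n3, np.nan)
    A = np.where(both, 0.5 * (cq_con + cq_n3), np.nan)
    M_norm = cyclic_loess_normalize(M, A, wide["plate"].to_numpy(), span=span)
    q_low, q_high, flags = adaptive_cutoff(M_norm, A, taus=taus, degree=degree)

    results: list[ScreenResult] = []
    for i, assay in enumerate(wide.index):
        if both[i]:
            call = {"above": "up", "below": "down", "inside": "unchanged"}[flags[i]]
            fc = _signed_fc(M_norm[i])
        elif dn3[i]:
            call, fc = "n3_only", math.nan
        elif dcon[i]:
            call, fc = "con_only", math.nan
        else:
            call, fc = "undetected", math.nan
        defined = [v for v in (cq_con[i], cq_n3[i]) if np.isfinite(v)]
        results.append(
            ScreenResult(
                assay_id=str(assay),
                detected_con=bool(dcon[i]),
                detected_n3=bool(dn3[i]),
                M=float(M[i]),
                A=float(A[i]),
                M_norm=float(M_norm[i]),
                q_low=float(q_low[i]),
                q_high=float(q_high[i]),
                call=call,
                signed_fc=float(fc),
                median_cq=float(np.median(defined)) if defined else math.nan,
            )
        )

    n_screened = len(results) if n_screened is None else n_screened
    n_det_con = int(dcon.sum())
    n_det_n3 = int(dn3.sum())
    n_common = int(both.sum())
    n_up = sum(r.call == "up" for r in results)
    n_down = sum(r.call == "down" for r in results)
    n_uc = sum(r.call == "con_only" for r in results)
    n_un = sum(r.call == "n3_only" for r in results)
    summary = VennSummary(
        n_screened=n_screened,
        n_det_con=n_det_con,
        n_det_n3=n_det_n3,
        n_common=n_common,
        n_union=n_det_con + n_det_n3 - n_common,
        n_unique_con=n_uc,
        n_unique_n3=n_un,
        n_diff_common=n_up + n_down,
        n_up=n_up,
        n_down=n_down,
        n_diff_total=n_uc + n_un + n_up + n_down,
    )
    return results, summary


def write_screen_results(results: list[ScreenResult], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in results]).to_csv(path, sep="\t", index=False)


def ma_plot(results: list[ScreenResult], path: str | Path) -> None:
    """MA scatter with the fitted quantile envelope, colored by call."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.DataFrame([asdict(r) for r in results]).dropna(subset=["M_norm"])
    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {"up": "tab:red", "down": "tab:blue", "unchanged": "0.6"}
    for call, grp in df.groupby("call"):
        ax.scatter(grp["A"], grp["M_norm"], s=8, label=call,
                   color=colors.get(call, "k"), alpha=0.7)
    order = df.sort_values("A")
    ax.plot(order["A"], order["q_low"], "k--", lw=1)
    ax.plot(order["A"], order["q_high"], "k--", lw=1)
    ax.set_xlabel("A (mean Cq)")
    ax.set_ylabel("normalized M (log2 FC)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def quantile_pinball_lp(
    y: np.ndarray, X: np.ndarray, tau: float
) -> np.ndarray:  # pragma: no cover - exercised via tests as an oracle helper
    """Exact LP solution of the pinball-loss polynomial quantile fit.

    Kept in the library as a slow, exact alternative solver; the main path
    uses iteratively reweighted least squares via statsmodels.
    """
    n, p = X.shape
    # variables: beta (p, free) as beta+ - beta-, residual splits u, v >= 0
    c = np.concatenate([np.zeros(2 * p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = np.hstack([X, -X, np.eye(n), -np.eye(n)])
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, method="highs")
    if not res.success:
        raise FitError(f"LP quantile fit failed: {res.message}")
    beta = res.x[:p] - res.x[p : 2 * p]
    return beta
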