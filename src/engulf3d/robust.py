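"""Robust outlier removal (ROUT) and tidy per-cell summary tables.

ROUT combines a robust fit with an FDR-controlled outlier test. For a
single column of values the "regression" degenerates to a robust location:
the location is fitted by iteratively reweighted minimization of the
Lorentzian loss Σ log(1 + (r/RSDR)²), the robust standard deviation of the
residuals (RSDR) is the 68.27th percentile of |residuals| with the small-
sample correction n/(n − K) (K = 1 fitted parameter), and residuals are
then tested outermost-inward with a t statistic against the
Benjamini–Hochberg-style schedule αᵢ = Q·i/n. All points more extreme than
the first failure are flagged; Q is the maximum desired false discovery
rate (default 1%).

Group-level inferential tests (ANOVA, posthoc comparisons) are deliberately
not reimplemented here: the summary emits tidy per-cell tables formatted
for external statistics software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Engulf3dError
from .engulfment import EngulfmentResult

#: Percentile of |residuals| that equals one SD for Gaussian data.
_RSDR_PERCENTILE = 68.27


@dataclass
class OutlierReport:
    """Result of ROUT outlier detection on one column of values."""

    kept: np.ndarray
    flagged: np.ndarray
    flagged_indices: np.ndarray
    robust_location: float
    rsdr: float
    q_used: float

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)

    def to_record(self) -> dict:
        return {
            "n_input": len(self.kept) + len(self.flagged),
            "n_flagged": self.n_flagged,
            "robust_location": self.robust_location,
            "rsdr": self.rsdr,
            "q": self.q_used,
            "flagged_values": self.flagged.tolist(),
        }


def _robust_location(x: np.ndarray, max_iter: int = 100, tol: float = 1e-12):
    """IRLS fit of a constant under the Lorentzian loss; returns (m, rsdr)."""
    n = len(x)
    m = float(np.median(x))
    rsdr = 0.0
    for _ in range(max_iter):
        r = x - m
        rsdr = float(np.percentile(np.abs(r), _RSDR_PERCENTILE)) * n / (n - 1)
        if rsdr <= 0:
            return m, 0.0
        w = 1.0 / (1.0 + (r / rsdr) ** 2)
        m_new = float(np.sum(w * x) / np.sum(w))
        if abs(m_new - m) < tol * max(1.0, abs(m)):
            m = m_new
            break
        m = m_new
    r = x - m
    rsdr = float(np.percentile(np.abs(r), _RSDR_PERCENTILE)) * n / (n - 1)
    return m, rsdr


def rout_outliers(values: Sequence[float], q: float = 0.01) -> OutlierReport:
    """Flag outliers in a single sample with the ROUT procedure.

    Points are tested from the most extreme inward: the i-th most extreme
    residual (i = 1, 2, …) is an outlier when its two-sided t probability
    (df = n − 1) falls below αᵢ = q·i/n; testing stops at the first point
    that is not an outlier, so the flagged set is always the outermost run.
    The procedure is permutation-invariant and affine-equivariant. With all
    values equal (RSDR = 0) nothing is flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise Engulf3dError("rout_outliers expects a 1D sequence")
    n = len(x)
    if n < 3:
        raise Engulf3dError(f"ROUT requires n ≥ 3 values, got {n}")
    if not (0 < q < 0.5):
        raise Engulf3dError("q must be in (0, 0.5)")

    m, rsdr = _robust_location(x)
    if rsdr <= 0:
        return OutlierReport(
            kept=x.copy(),
            flagged=np.empty(0),
            flagged_indices=np.empty(0, dtype=int),
            robust_location=m,
            rsdr=0.0,
            q_used=q,
        )

    r = x - m
    order = np.argsort(-np.abs(r), kind="stable")  # outermost first
    t = np.abs(r[order]) / rsdr
    p = 2.0 * stats.t.sf(t, df=n - 1)
    flagged_idx: list[int] = []
    for i, (idx, pi) in enumerate(zip(order, p), start=1):
        if pi < q * i / n:
            flagged_idx.append(int(idx))
        else:
            break
    flagged = np.array(sorted(flagged_idx), dtype=int)
    keep_mask = np.ones(n, dtype=bool)
    keep_mask[flagged] = False
    return OutlierReport(
        kept=x[keep_mask],
        flagged=x[~keep_mask],
        flagged_indices=flagged,
        robust_location=m,
        rsdr=rsdr,
        q_used=q,
    )


def per_cell_summary(
    results: Sequence[EngulfmentResult],
    group_labels: Sequence[str],
    mouse_labels: Optional[Sequence[str]] = None,
    extra_columns: Optional[dict[str, Sequence[float]]] = None,
    rout_enabled: bool = True,
    q: float = 0.01,
    known_groups: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, dict[str, OutlierReport]]:
    """Tidy per-cell table (one row per cell) ready for external statistics.

    Each row carries the cell's group, mouse, and engulfment index (plus any
    ``extra_columns``, e.g. reporter ratios). When ``rout_enabled``, ROUT at
    FDR ``q`` is applied to the engulfment index *within each group* — the
    conservative reading, since groups may genuinely differ — and flagged
    cells are dropped from the emitted table (their identity is returned in
    the per-group reports). Groups too small for ROUT (n < 3) pass through
    unfiltered.
    """
    if not results:
        raise Engulf3dError("per_cell_summary requires at least one result")
    if len(group_labels) != len(results):
        raise Engulf3dError("group_labels must match results in length")
    if mouse_labels is not None and len(mouse_labels) != len(results):
        raise Engulf3dError("mouse_labels must match results in length")
    if known_groups is not None:
        bad = sorted(set(group_labels) - set(known_groups))
        if bad:
            raise Engulf3dError(f"unknown group label(s): {bad}")

    df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "group": list(group_labels),
            "mouse": list(mouse_labels) if mouse_labels is not None else "",
            "cell_volume_um3": [r.cell_volume_um3 for r in results],
            "internalized_volume_um3": [r.internalized_volume_um3 for r in results],
            "engulfment_index": [r.engulfment_index for r in results],
        }
    )
    if extra_columns:
        for name, vals in extra_columns.items():
            if len(vals) != len(results):
                raise Engulf3dError(f"extra column {name!r} length mismatch")
            df[name] = list(vals)

    reports: dict[str, OutlierReport] = {}
    if rout_enabled:
        keep = np.ones(len(df), dtype=bool)
        for group, sub in df.groupby("group", sort=True):
            if len(sub) < 3:
                continue
            rep = rout_outliers(sub["engulfment_index"].to_numpy(), q=q)
            reports[str(group)] = rep
            flagged_rows = sub.index.to_numpy()[rep.flagged_indices]
            keep[flagged_rows] = False
        df = df[keep].reset_index(drop=True)
    return df, reports
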