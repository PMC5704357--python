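"""Agreement between thresholding output and reference (SPARCC) scores.

Confusion tables with sensitivity/specificity, reconstruction of a 2×2
table from published aggregate counts, Spearman rank correlation between
scores and lesion metrics, and cohort aggregation of lesion-positive-subset
means to all-set means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AgreementTable:
    """2×2 confusion counts; reference defines the truth axis."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        """TP / (TP + FN); ``None`` when there are no reference positives."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        """TN / (TN + FP); ``None`` when there are no reference negatives."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    def as_percent(self) -> tuple[int | None, int | None]:
        """(sensitivity, specificity) rounded to integer percent."""
        se, sp = self.sensitivity, self.specificity
        return (
            None if se is None else round(100 * se),
            None if sp is None else round(100 * sp),
        )


def confusion(reference: Sequence[bool], test: Sequence[bool]) -> AgreementTable:
    """Cross-tabulate per-unit reference vs test positivity."""
    ref = np.asarray(reference, dtype=bool)
    tst = np.asarray(test, dtype=bool)
    if ref.shape != tst.shape or ref.ndim != 1 or ref.size == 0:
        raise ValueError(
            f"label lists must be equal-length and non-empty "
            f"(got {ref.shape} vs {tst.shape})"
        )
    return AgreementTable(
        tp=int((ref & tst).sum()),
        fp=int((~ref & tst).sum()),
        fn=int((ref & ~tst).sum()),
        tn=int((~ref & ~tst).sum()),
    )


def confusion_from_counts(n_total: int, n_ref_pos: int, n_test_pos: int,
                          n_agree_neg: int) -> AgreementTable:
    """Reconstruct the 2×2 table from aggregate counts.

    Given the number of units, reference positives, test positives and
    agreed negatives (both methods negative): TN = agreed negatives,
    FP = reference negatives − TN, TP = test positives − FP,
    FN = reference positives − TP.  Inconsistent counts (any implied cell
    negative) raise ``ValueError`` naming the cell.
    """
    tn = n_agree_neg
    fp = (n_total - n_ref_pos) - tn
    if fp < 0:
        raise ValueError(f"inconsistent counts: implied FP = {fp} < 0")
    tp = n_test_pos - fp
    if tp < 0:
        raise ValueError(f"inconsistent counts: implied TP = {tp} < 0")
    fn = n_ref_pos - tp
    if fn < 0:
        raise ValueError(f"inconsistent counts: implied FN = {fn} < 0")
    if tp + fp + fn + tn != n_total:
        raise ValueError("inconsistent counts: cells do not sum to n_total")
    return AgreementTable(tp=tp, fp=fp, fn=fn, tn=tn)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, ties averaged).

    Returns ``nan`` when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return math.nan
    rho, _ = sps.spearmanr(x, y)
    return float(rho)


def aggregate_cohort(values: Sequence[float], n_total: int,
                     include_zeros: bool = True
                     ) -> tuple[float, float, float]:
    """Extend a lesion-positive-subset mean/range to the whole cohort.

    ``values`` are the metric for the positive sets only.  With
    ``include_zeros`` the remaining ``n_total − len(values)`` sets enter as
    exact zeros: mean = sum(values)/n_total, range extended to 0.  Without,
    the plain mean and range of ``values`` are returned.
    """
    vals = np.asarray(values, dtype=float)
    if n_total <= 0:
        raise ValueError("n_total must be >= 1")
    if len(vals) > n_total:
        raise ValueError("more positive values than total units")
    if not include_zeros:
        if len(vals) == 0:
            raise ValueError("no values to aggregate")
        return float(vals.mean()), float(vals.min()), float(vals.max())
    mean = float(vals.sum() / n_total)
    if len(vals) == n_total and len(vals) > 0:
        lo = float(vals.min())
    else:
        lo = 0.0
    hi = float(vals.max()) if len(vals) else 0.0
    return mean, lo, hi


def tidy_results_table(results: Sequence, labels: pd.DataFrame | None = None
                       ) -> pd.DataFrame:
    """Per-set metrics as a tidy table for external modelling (e.g. an LMM
    of metric vs score with patient as a random effect).

    ``results`` are ``QuantResult`` objects; ``labels`` (optional) is a
    frame with ``image_set`` and ``score`` columns to merge on image id.
    """
    rows = [r.to_dict() for r in results]
    df = pd.DataFrame(rows)
    if labels is not None:
        lab = labels.rename(columns={"image_set": "image_id"})
        df = df.merge(lab, on="image_id", how="left")
    return df
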