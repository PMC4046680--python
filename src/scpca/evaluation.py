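"""Power and ROC evaluation of SNP-set association methods on simulated
datasets with known causal status."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["RocCurve", "power", "roc_points", "auc", "power_table"]


@dataclass
class RocCurve:
    """ROC points from sweeping the p-value threshold: causal datasets are
    positives, null datasets negatives."""

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


def power(pvalues_causal: np.ndarray, alpha: float = 0.05) -> float:
    """Proportion of causal datasets detected: #{p < alpha} / N.

    Strict inequality, so p-values exactly equal to alpha (or to 1 when
    alpha = 1) do not count as detections.
    """
    p = np.asarray(pvalues_causal, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return float(np.mean(p < alpha))


def roc_points(pvalues_causal: np.ndarray, pvalues_null: np.ndarray) -> RocCurve:
    """ROC curve over all distinct p-value thresholds (p <= t calls a hit),
    with (0,0) and (1,1) endpoints appended."""
    pc = np.asarray(pvalues_causal, dtype=float)
    pn = np.asarray(pvalues_null, dtype=float)
    if pc.size == 0 or pn.size == 0:
        raise ValueError("both causal and null p-value vectors must be non-empty")
    thresholds = np.unique(np.concatenate([pc, pn]))
    tpr = [(pc <= t).mean() for t in thresholds]
    fpr = [(pn <= t).mean() for t in thresholds]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return RocCurve(fpr=fpr, tpr=tpr)


def auc(curve: RocCurve) -> float:
    """Area under the ROC curve by the trapezoid rule."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def power_table(
    results: pd.DataFrame,
    alpha: float = 0.05,
    group_cols: Sequence[str] = ("method", "risk_level"),
) -> pd.DataFrame:
    """Per-(method, risk level) power from a long results table.

    ``results`` needs columns ``p_value`` and ``is_causal`` plus the grouping
    columns; power is computed over causal datasets only.
    """
    causal = results[results["is_causal"]]
    rows = []
    for keys, grp in causal.groupby(list(group_cols)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            dict(
                zip(group_cols, keys),
                power=power(grp["p_value"].to_numpy(), alpha),
                n_causal=len(grp),
                alpha=alpha,
            )
        )
    return pd.DataFrame(rows)
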