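"""Desk-scale evaluation reports: two-group testing and ROC construction.

The benchmark's diagnostic question is whether spiked-proteome features are
classified as differentially expressed while background features are not.
A plain Welch t-test on log2 intensities stands in for moderated testing
here; ROC curves are computed over significance thresholds with the
spiked proteome as the positive class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError


def welch_pvalues(
    log2_matrix: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.Series:
    """Per-feature Welch t-test p-values between two channel groups."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ConfigurationError("each group needs at least 2 replicate channels")
    a = log2_matrix[group_a].to_numpy(dtype=float)
    b = log2_matrix[group_b].to_numpy(dtype=float)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    return pd.Series(np.asarray(res.pvalue, dtype=float), index=log2_matrix.index)


def roc_from_groups(pvalues, truth_labels) -> pd.DataFrame:
    """ROC points over p-value thresholds.

    ``truth_labels`` is boolean (True = truly changing, e.g. spiked
    proteome).  The true positive rate is the fraction of true features
    significant at each threshold; the false positive rate the fraction of
    null features significant at the same threshold.  Points are monotone
    non-decreasing in both coordinates and the output is deterministic.
    """
    p = np.asarray(pvalues, dtype=float)
    truth = np.asarray(truth_labels, dtype=bool)
    ok = np.isfinite(p)
    p, truth = p[ok], truth[ok]
    if truth.all() or (~truth).all():
        raise ConfigurationError("need both true and null features for a ROC curve")
    order = np.argsort(p, kind="stable")
    p, truth = p[order], truth[order]
    n_true = truth.sum()
    n_null = len(truth) - n_true
    tpr = np.cumsum(truth) / n_true
    fpr = np.cumsum(~truth) / n_null
    # collapse tied thresholds to their last (most inclusive) point
    last_of_tie = np.r_[p[1:] != p[:-1], True]
    points = pd.DataFrame(
        {"threshold": p[last_of_tie], "fpr": fpr[last_of_tie], "tpr": tpr[last_of_tie]}
    )
    return points


def roc_auc(points: pd.DataFrame) -> float:
    """Trapezoidal area under a ROC point set, anchored at (0,0) and (1,1)."""
    fpr = np.r_[0.0, points["fpr"].to_numpy(), 1.0]
    tpr = np.r_[0.0, points["tpr"].to_numpy(), 1.0]
    return float(np.trapezoid(tpr, fpr))
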