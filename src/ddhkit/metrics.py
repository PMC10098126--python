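"""Performance and agreement statistics for diagnostic comparisons.

Covers the statistics used to score a rater (or the software) against a
reference standard: confusion-count rates and the two-point ROC AUC of a
single-threshold binary rater, DeLong's paired test for correlated AUCs,
Bland-Altman limits of agreement, the intraclass correlation coefficient
(two-way random effects, absolute agreement, single measurement — the
standard test-retest form), Cohen's linearly weighted kappa, and the
multi-class confusion matrix.

Rates are returned on the percentage scale; AUC, ICC and kappa on their
natural scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .core import UndefinedStatisticError, ValidationError

__all__ = [
    "BinaryConfusion",
    "binary_metrics",
    "delong_paired",
    "bland_altman",
    "icc_agreement",
    "weighted_kappa",
    "multiclass_confusion",
]


@dataclass(frozen=True)
class BinaryConfusion:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def binary_metrics(c: BinaryConfusion) -> Dict[str, float]:
    """Sensitivity, specificity, accuracy (in %) and two-point ROC AUC.

    A single-threshold binary rater traces a two-point ROC; its trapezoidal
    AUC is (sensitivity + specificity) / 2 on the proportion scale.
    """
    if c.tp + c.fn == 0:
        raise UndefinedStatisticError("sensitivity undefined: no positives")
    if c.tn + c.fp == 0:
        raise UndefinedStatisticError("specificity undefined: no negatives")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return {
        "sensitivity_pct": 100.0 * sens,
        "specificity_pct": 100.0 * spec,
        "accuracy_pct": 100.0 * (c.tp + c.tn) / c.total,
        "auc": (sens + spec) / 2.0,
    }


def _placements(truth: np.ndarray, scores: np.ndarray):
    """Mann-Whitney AUC and DeLong placement values V10 (per positive) and
    V01 (per negative)."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_paired(
    truth: Sequence[int], scores_a: Sequence[float], scores_b: Sequence[float]
) -> Dict[str, float]:
    """DeLong's test for two correlated ROC AUCs measured on the same cases.

    Uses the placement-value estimator of the AUC covariance; returns both
    AUCs, the z statistic, and the two-sided normal p-value.  When the
    paired variance of the difference is zero (e.g. identical scores) the
    test degenerates to z = 0, p = 1 for a zero difference.
    """
    t = np.asarray(truth, dtype=int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (t.shape == a.shape == b.shape):
        raise ValidationError("truth and score vectors must be aligned")
    if not set(np.unique(t)) <= {0, 1}:
        raise ValidationError("truth must be binary 0/1")
    m = int((t == 1).sum())
    n = int((t == 0).sum())
    if m == 0 or n == 0:
        raise UndefinedStatisticError(
            "AUC undefined: need at least one positive and one negative"
        )
    auc_a, v10_a, v01_a = _placements(t, a)
    auc_b, v10_b, v01_b = _placements(t, b)

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else _inf_with_sign(diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / float(np.sqrt(var))
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p": float(p)}


def _inf_with_sign(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> Dict[str, float]:
    """Bland-Altman agreement of paired measurements.

    bias = mean(a - b); 95% limits of agreement = bias ± 1.96·SD(a − b)
    (sample SD, n − 1); ``bias_p`` from a two-sided one-sample t-test of
    the differences against zero (p = 1 when the differences are constant
    and zero, p = 0 when constant and non-zero).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired sequences must be equal-length 1-D")
    if x.size < 2:
        raise UndefinedStatisticError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("missing/non-finite values not allowed")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        p = 1.0 if bias == 0.0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "bias_p": p,
    }


def icc_agreement(a: Sequence[float], b: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    The standard form for test-retest agreement of continuous measurements.
    Raises :class:`UndefinedStatisticError` when there is no
    between-subject variance (the coefficient is then undefined).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired sequences must be equal-length 1-D")
    if x.size < 3:
        raise UndefinedStatisticError("need at least 3 subjects")
    subject_means = (x + y) / 2.0
    if np.allclose(subject_means, subject_means[0]):
        raise UndefinedStatisticError("zero between-subject variance")
    import pingouin as pg  # deferred: pingouin import is heavy

    n = x.size
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([x, y]),
        }
    )
    res = pg.intraclass_corr(
        data=df, targets="subject", raters="rater", ratings="score"
    )
    # the absolute-agreement single-measure row is labelled ICC2 or ICC(A,1)
    # depending on the pingouin version
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


def weighted_kappa(
    r1: Sequence, r2: Sequence, categories: Sequence
) -> float:
    """Cohen's linearly weighted kappa for two raters on ordered categories.

    Weights w_ij = |i − j| / (k − 1); kappa = 1 − Σ w·O / Σ w·E with O the
    observed and E the chance-expected (marginal-product) proportions.
    """
    cats = list(categories)
    if len(cats) < 2:
        raise ValidationError("need at least 2 categories")
    a = list(r1)
    b = list(r2)
    if len(a) != len(b) or not a:
        raise ValidationError("rating sequences must be equal-length, non-empty")
    bad = [v for v in a + b if v not in cats]
    if bad:
        raise ValidationError(f"rating {bad[0]!r} not in the category list")
    if len(set(a)) < 2 or len(set(b)) < 2:
        raise UndefinedStatisticError(
            "kappa undefined: a rater used a single category"
        )
    return float(cohen_kappa_score(a, b, labels=cats, weights="linear"))


def multiclass_confusion(
    truth: Sequence, pred: Sequence, labels: Sequence
) -> pd.DataFrame:
    """Confusion matrix (rows = truth, columns = prediction) over ``labels``."""
    labs = list(labels)
    t = list(truth)
    p = list(pred)
    if len(t) != len(p):
        raise ValidationError("truth and pred must be equal-length")
    bad = [v for v in t + p if v not in labs]
    if bad:
        raise ValidationError(f"unknown label {bad[0]!r}")
    if not t:
        m = np.zeros((len(labs), len(labs)), dtype=int)
    else:
        m = confusion_matrix(t, p, labels=labs)
    return pd.DataFrame(m, index=labs, columns=labs)
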