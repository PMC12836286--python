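"""Evaluation metrics and statistical machinery.

Covers the full reporting stack for pooled out-of-fold predictions:
confusion metrics at a probability threshold, ROC/AUC (Mann-Whitney
with half credit for ties), exact Clopper-Pearson binomial intervals,
BCa bootstrap confidence intervals for the AUC, DeLong's test for
paired AUC comparison, and a paired t-test on per-node correctness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "confusion_metrics",
    "roc_auc",
    "roc_curve_points",
    "clopper_pearson",
    "bca_bootstrap_auc_ci",
    "delong_test",
    "paired_correctness_test",
    "evaluation_report",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    return labels


def confusion_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """SEN, SPE, ACC, PPV, NPV at ``score >= threshold``.

    Undefined-denominator PPV/NPV are reported as NaN with a warning,
    never silently as 0.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if len(labels) == 0:
        raise ValidationError("empty prediction set")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    out: dict[str, float] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    out["SEN"] = tp / (tp + fn) if tp + fn else float("nan")
    out["SPE"] = tn / (tn + fp) if tn + fp else float("nan")
    out["ACC"] = (tp + tn) / len(labels)
    for name, num, den in (("PPV", tp, tp + fp), ("NPV", tn, tn + fn)):
        if den == 0:
            logger.warning("%s undefined (zero denominator)", name)
            out[name] = float("nan")
        else:
            out[name] = num / den
    return out


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic with half credit for ties."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes")
    ranks = stats.rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve_points(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(FPR, TPR, thresholds) sweeping the threshold over unique scores."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(1 - sorted_labels)[distinct]
    n_pos = max(int(labels.sum()), 1)
    n_neg = max(int((1 - labels).sum()), 1)
    fpr = np.r_[0.0, fps / n_neg]
    tpr = np.r_[0.0, tps / n_pos]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return fpr, tpr, thresholds


def clopper_pearson(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact central binomial interval via beta quantiles."""
    if not 0 < level < 1:
        raise ValidationError("level must be in (0, 1)")
    if n < 1 or not 0 <= successes <= n:
        raise ValidationError("need 0 <= successes <= n, n >= 1")
    alpha = 1.0 - level
    x = int(successes)
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def bca_bootstrap_auc_ci(
    labels: np.ndarray,
    scores: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for the AUC.

    Nodes are resampled with replacement; resamples missing a class are
    redrawn.  The bias correction z0 comes from the fraction of
    bootstrap AUCs below the point estimate, the acceleration from
    jackknife AUCs.  A degenerate bootstrap distribution collapses the
    interval to the point estimate.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    n = len(labels)
    theta_hat = roc_auc(labels, scores)
    rng = np.random.default_rng(np.random.PCG64(seed))

    boot = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
        boot[b] = roc_auc(lab, scores[idx])

    if np.all(boot == boot[0]):
        return theta_hat, theta_hat

    # bias correction
    prop = np.mean(boot < theta_hat)
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1.0 - 1.0 / (2 * n_boot))
    z0 = stats.norm.ppf(prop)

    # acceleration from jackknife
    jack = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        lab = labels[keep]
        if 0 < lab.sum() < len(lab):
            jack[i] = roc_auc(lab, scores[keep])
        else:
            jack[i] = theta_hat
        keep[i] = True
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = (d**3).sum() / (6.0 * denom) if denom > 0 else 0.0

    return _bca_interval(boot, z0, a, level)


def _bca_interval(
    boot: np.ndarray, z0: float, a: float, level: float
) -> tuple[float, float]:
    """Map BCa-adjusted percentiles through the bootstrap distribution.

    With ``z0 = 0`` and ``a = 0`` this reduces to the plain percentile
    interval.
    """
    alpha = 1.0 - level
    out = []
    for q in (alpha / 2, 1 - alpha / 2):
        zq = stats.norm.ppf(q)
        adj = z0 + (z0 + zq) / (1 - a * (z0 + zq))
        out.append(float(np.quantile(boot, stats.norm.cdf(adj))))
    return out[0], out[1]


def _placements(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # midrank formulation (Sun & Xu)
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_test(
    labels: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray
) -> dict[str, float]:
    """DeLong's paired test for two correlated AUCs on the same cases.

    Returns AUC_A, AUC_B, z and the two-sided normal p-value.  A zero
    variance with zero AUC difference yields p = 1; nonzero difference
    with zero variance is flagged degenerate (p = NaN).
    """
    labels = _check_binary(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if not len(labels) == len(scores_a) == len(scores_b):
        raise ValidationError("score sets must cover the same cases")
    v10_a, v01_a = _placements(labels, scores_a)
    v10_b, v01_b = _placements(labels, scores_b)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m = len(v10_a)
    n = len(v01_a)
    if m < 2 or n < 2:
        raise ValidationError("DeLong needs >= 2 cases per class")
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    s = s10 / m + s01 / n
    var = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    delta = auc_a - auc_b
    if var <= 0:
        if delta == 0:
            z, p = 0.0, 1.0
        else:
            logger.warning("DeLong degenerate: zero variance, nonzero AUC delta")
            z, p = float("inf") if delta > 0 else float("-inf"), float("nan")
    else:
        z = delta / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": float(z), "p": p, "var": var}


def paired_correctness_test(
    correct_a: np.ndarray, correct_b: np.ndarray
) -> dict[str, float]:
    """Paired t-test on per-node 0/1 correctness indicators.

    All-zero differences give p = 1; nonzero mean with zero spread is
    flagged degenerate with p -> 0.
    """
    a = np.asarray(correct_a, dtype=float)
    b = np.asarray(correct_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("correctness vectors must have equal length")
    if len(a) < 2:
        raise ValidationError("need at least two paired observations")
    d = a - b
    if np.all(d == 0):
        return {"t": 0.0, "p": 1.0, "mean_diff": 0.0}
    sd = d.std(ddof=1)
    if sd == 0:
        logger.warning("paired test degenerate: constant nonzero differences")
        return {"t": math.copysign(math.inf, d.mean()), "p": 0.0, "mean_diff": float(d.mean())}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue), "mean_diff": float(d.mean())}


@dataclass
class EvaluationReport:
    metrics: dict[str, float]
    ci: dict[str, tuple[float, float]]
    auc: float
    auc_ci: tuple[float, float]
    n: int = 0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "metrics": self.metrics,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            **self.extra,
        }


def evaluation_report(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
    pooled_n_cis: bool = False,
) -> EvaluationReport:
    """Full report: confusion metrics, Clopper-Pearson CIs, AUC + BCa CI.

    By default SEN/SPE intervals use their class-specific denominators;
    ``pooled_n_cis`` switches to the pooled node count (a compatibility
    convention for interval widths computed on the full cohort size).
    """
    labels = _check_binary(labels)
    m = confusion_metrics(labels, scores, threshold)
    n = len(labels)
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    ci: dict[str, tuple[float, float]] = {}
    denom = {"SEN": n if pooled_n_cis else n_pos, "SPE": n if pooled_n_cis else n_neg, "ACC": n}
    for key in ("SEN", "SPE", "ACC"):
        d = denom[key]
        if d > 0 and not math.isnan(m[key]):
            ci[key] = clopper_pearson(round(m[key] * d), d, level)
    auc = roc_auc(labels, scores)
    auc_ci = bca_bootstrap_auc_ci(labels, scores, n_boot=n_boot, level=level, seed=seed)
    return EvaluationReport(
        metrics={k: m[k] for k in ("SEN", "SPE", "ACC", "PPV", "NPV")},
        ci=ci,
        auc=auc,
        auc_ci=auc_ci,
        n=n,
        extra={"confusion": {k: m[k] for k in ("TP", "FP", "TN", "FN")}},
    )
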