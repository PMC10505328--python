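"""Agreement between predicted signature scores and self-reported HL:
Pearson correlation with Fisher-z confidence intervals for the continuous
score, ROC AUC with stratified-bootstrap intervals for the dichotomized
score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, pearsonr
from sklearn.metrics import roc_auc_score

from ._containers import ValidationError


@dataclass
class ValidationReport:
    sample_label: str
    metric: str  # 'pearson_r' or 'auc'
    estimate: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValidationError("confidence interval does not bracket estimate")


def pearson_with_ci(
    pred, obs, conf: float = 0.95, sample_label: str = "baseline"
) -> ValidationReport:
    """Sample Pearson r with the Fisher-z interval
    tanh(atanh(r) +/- z_{1-(1-conf)/2} / sqrt(n-3))."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    n = len(pred)
    if n < 4 or len(obs) != n:
        raise ValidationError("need >= 4 aligned finite observations")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValidationError("non-finite values in inputs")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValidationError("zero variance in pred or obs")
    r = float(pearsonr(pred, obs).statistic)
    z = norm.ppf(1.0 - (1.0 - conf) / 2.0)
    half = z / np.sqrt(n - 3)
    lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
    return ValidationReport(sample_label, "pearson_r", r, float(lo), float(hi), n)


def roc_auc_with_ci(
    pred, labels, conf: float = 0.95, n_boot: int = 2000, seed: int = 0,
    sample_label: str = "baseline",
) -> ValidationReport:
    """Mann-Whitney AUC (ties count 1/2) with a seeded stratified-bootstrap
    percentile confidence interval."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(labels).astype(int)
    n = len(pred)
    if len(y) != n:
        raise ValidationError("pred and labels must align")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    auc = float(roc_auc_score(y, pred))

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        boots[b] = roc_auc_score(y[idx], pred[idx])
    a = (1.0 - conf) / 2.0
    lo, hi = np.quantile(boots, [a, 1.0 - a])
    lo, hi = min(lo, auc), max(hi, auc)
    return ValidationReport(sample_label, "auc", auc, float(lo), float(hi), n)
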