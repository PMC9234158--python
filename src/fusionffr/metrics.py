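"""Lesion metrics and diagnostic-performance statistics.

Functional significance is FFR <= 0.80 (inclusive).  Diagnostic accuracy,
sensitivity, specificity, PPV and NPV are simple proportions with exact
Clopper-Pearson 95% confidence intervals; correlation comparisons use
Steiger's Z-test for two dependent correlations sharing a variable; ROC
curves are compared with DeLong's test; agreement uses Bland-Altman limits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contours import ValidationError

FFR_CUTOFF = 0.80


def _round_half_up(x: float, ndigits: int = 1) -> float:
    scale = 10 ** ndigits
    return np.floor(x * scale + 0.5) / scale


# ---------------------------------------------------------------------------
# lesion metrics
# ---------------------------------------------------------------------------

@dataclass
class LesionMetrics:
    mean_reference_lumen_area: float
    minimal_lumen_area: float
    area_stenosis_pct: float
    minimal_lumen_diameter: float
    diameter_stenosis_pct: float


def area_stenosis(mean_ref_area: float, mla: float) -> float:
    """Percent area stenosis: (reference - minimal) / reference * 100."""
    if mean_ref_area <= 0:
        raise ValidationError("reference area must be > 0")
    if not (0 < mla <= mean_ref_area):
        raise ValidationError("minimal lumen area must be in (0, reference]")
    return (mean_ref_area - mla) / mean_ref_area * 100.0


def lesion_metrics_from_areas(areas_mm2: np.ndarray,
                              lesion_slice: slice | None = None) -> LesionMetrics:
    """Summarize a lumen-area profile: the reference area is the mean of the
    largest proximal and distal areas flanking the lesion."""
    a = np.asarray(areas_mm2, dtype=float)
    k = int(np.argmin(a))
    mla = float(a[k])
    ref_prox = float(a[:k].max()) if k > 0 else mla
    ref_dist = float(a[k + 1:].max()) if k < len(a) - 1 else mla
    ref = (ref_prox + ref_dist) / 2.0
    ref = max(ref, mla)
    d_min = 2.0 * np.sqrt(mla / np.pi)
    d_ref = 2.0 * np.sqrt(ref / np.pi)
    return LesionMetrics(
        mean_reference_lumen_area=ref, minimal_lumen_area=mla,
        area_stenosis_pct=area_stenosis(ref, mla) if ref > 0 else 0.0,
        minimal_lumen_diameter=d_min,
        diameter_stenosis_pct=(1 - d_min / d_ref) * 100.0 if d_ref > 0 else 0.0)


def classify_significant(ffr: float) -> bool:
    """True iff the lesion is functionally significant (FFR <= 0.80)."""
    if not (0 < ffr <= 1.05):
        raise ValidationError(f"FFR {ffr} outside plausible range (0, 1.05]")
    return ffr <= FFR_CUTOFF


# ---------------------------------------------------------------------------
# confusion-matrix statistics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("counts must be non-negative")
        if self.total == 0:
            raise ValidationError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, truth, predicted) -> "ConfusionMatrix":
        t = np.asarray(truth, dtype=bool)
        p = np.asarray(predicted, dtype=bool)
        return cls(tp=int((t & p).sum()), fp=int((~t & p).sum()),
                   fn=int((t & ~p).sum()), tn=int((~t & ~p).sum()))


def confusion_from_rates(n: int, n_pos: int, sensitivity: float,
                         specificity: float) -> ConfusionMatrix:
    """Reconstruct integer counts implied by reported rates: tp and tn are
    the rates times the class sizes, rounded to the nearest integer."""
    if not (0 < n_pos < n):
        raise ValidationError("need 0 < n_pos < n")
    tp = int(round(sensitivity * n_pos))
    tn = int(round(specificity * (n - n_pos)))
    return ConfusionMatrix(tp=tp, fp=(n - n_pos) - tn, fn=n_pos - tp, tn=tn)


def clopper_pearson(k: int, n: int, alpha: float = 0.05):
    """Exact binomial confidence interval for a proportion."""
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(lo), float(hi)


@dataclass
class Proportion:
    value_pct: float
    ci_low_pct: float
    ci_high_pct: float
    numerator: int
    denominator: int

    def rounded(self) -> float:
        return _round_half_up(self.value_pct, 1)


@dataclass
class DiagnosticSummary:
    accuracy: Proportion
    sensitivity: Proportion | None
    specificity: Proportion | None
    ppv: Proportion | None
    npv: Proportion | None

    def as_dict(self) -> dict:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            p = getattr(self, name)
            out[name] = None if p is None else {
                "pct": p.rounded(), "ci": (_round_half_up(p.ci_low_pct, 1),
                                           _round_half_up(p.ci_high_pct, 1))}
        return out


def _proportion(k: int, n: int) -> Proportion | None:
    if n == 0:
        return None  # metric undefined, flagged rather than NaN-propagated
    lo, hi = clopper_pearson(k, n)
    return Proportion(value_pct=100.0 * k / n, ci_low_pct=100.0 * lo,
                      ci_high_pct=100.0 * hi, numerator=k, denominator=n)


def diagnostic_performance(cm: ConfusionMatrix) -> DiagnosticSummary:
    """Accuracy, sensitivity, specificity, PPV and NPV with exact 95% CIs."""
    return DiagnosticSummary(
        accuracy=_proportion(cm.tp + cm.tn, cm.total),
        sensitivity=_proportion(cm.tp, cm.tp + cm.fn),
        specificity=_proportion(cm.tn, cm.tn + cm.fp),
        ppv=_proportion(cm.tp, cm.tp + cm.fp),
        npv=_proportion(cm.tn, cm.tn + cm.fn))


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationComparison:
    r12: float
    r13: float
    r23: float
    z_statistic: float
    p_value: float


def steiger_z(r12: float, r13: float, r23: float, n: int) -> tuple:
    """Steiger's Z-test for two dependent correlations sharing variable 1.

    Fisher-transforms r12 and r13 and corrects for their dependence through
    r23; returns (z, two-sided p).
    """
    for r in (r12, r13, r23):
        if abs(r) >= 1.0:
            raise ValidationError("|r| must be < 1")
    if n <= 3:
        raise ValidationError("need n > 3")
    z12 = np.arctanh(r12)
    z13 = np.arctanh(r13)
    rm2 = (r12 ** 2 + r13 ** 2) / 2.0
    f = min((1.0 - r23) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - r23) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_correlations(x1, x2, x3) -> CorrelationComparison:
    """Compare corr(x1, x2) against corr(x1, x3) with Steiger's Z."""
    r12 = pearson_r(x1, x2)
    r13 = pearson_r(x1, x3)
    r23 = pearson_r(x2, x3)
    z, p = steiger_z(r12, r13, r23, len(np.asarray(x1)))
    return CorrelationComparison(r12=r12, r13=r13, r23=r23, z_statistic=z,
                                 p_value=p)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 0.5).

    Convention: higher score means higher risk; for an FFR estimate pass
    ``1 - ffr`` (lower FFR implies ischemia).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _placements(scores, labels):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg)
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos)
                    for q in neg])
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple:
    """DeLong's test for two paired AUCs; returns (auc_a, auc_b, z, p)."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10]))
    s01 = np.cov(np.stack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        raise ValidationError(
            "zero variance of the AUC difference (identical scores?)")
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def bland_altman(x, y) -> tuple:
    """Mean difference, SD of differences and 95% limits of agreement of
    y - x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need >= 3 paired values")
    d = y - x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, sd, (mean - 1.96 * sd, mean + 1.96 * sd)


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

def cohort_report(df, truth_col: str = "ffr",
                  pred_cols=("fusion_ffr", "ct_ffr", "oct_ffr"),
                  cutoff: float = FFR_CUTOFF) -> dict:
    """Full evaluation of computational-FFR columns against wire FFR:
    correlation, Bland-Altman agreement, AUC and confusion-matrix
    performance per predictor, plus pairwise Steiger/DeLong comparisons
    against the first predictor."""
    truth_vals = np.asarray(df[truth_col], dtype=float)
    truth = truth_vals <= cutoff
    out = {"n": int(len(df)), "prevalence": float(truth.mean()),
           "cutoff": cutoff, "predictors": {}, "comparisons": {}}
    for col in pred_cols:
        v = np.asarray(df[col], dtype=float)
        cm = ConfusionMatrix.from_labels(truth, v <= cutoff)
        md, sd, loa = bland_altman(v, truth_vals)
        out["predictors"][col] = {
            "r": pearson_r(truth_vals, v),
            "auc": roc_auc(1.0 - v, truth),
            "mean_difference": md, "sd_difference": sd,
            "limits_of_agreement": loa,
            "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "performance": diagnostic_performance(cm).as_dict(),
        }
    ref = pred_cols[0]
    for col in pred_cols[1:]:
        cc = compare_correlations(truth_vals, np.asarray(df[ref], float),
                                  np.asarray(df[col], float))
        auc_a, auc_b, z, p = delong_test(1.0 - np.asarray(df[ref], float),
                                         1.0 - np.asarray(df[col], float),
                                         truth)
        out["comparisons"][f"{ref}_vs_{col}"] = {
            "steiger_z": cc.z_statistic, "steiger_p": cc.p_value,
            "delong_z": z, "delong_p": p,
            "auc_a": auc_a, "auc_b": auc_b,
        }
    return out
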