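"""Examiner-agreement battery for paired (panel, software) scores.

Validating an automated grader against an expert panel uses a standard
method-comparison toolkit:

* pass/fail diagnostics (sensitivity, specificity, PPV, NPV) with the panel
  as ground truth and "pass" as the positive class,
* ROC and precision–recall curves sweeping the software score as threshold,
* Cohen's kappa and linear/quadratic weighted kappa on the letter grades,
* ICC(3,k) — two-way mixed effects, consistency, average measures — with a
  95% CI from F-distribution bounds,
* Spearman's rho and Kendall's tau-b rank correlations with p-values,
* Bland–Altman bias and 95% limits of agreement,
* agreement on the worst/top score tails,
* the 5×5 ordinal confusion matrix over letter grades, and per-grader
  descriptive statistics.

Undefined quantities (empty class, zero variance) are reported as NaN
rather than raised, so a report can always be produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import precision_recall_curve as _sk_pr_curve
from sklearn.metrics import roc_curve as _sk_roc_curve

from .grading import DEFAULT_CUTOFF, letter_grade

__all__ = [
    "PairedScores",
    "BinaryConfusion",
    "OrdinalConfusion",
    "DiagnosticMetrics",
    "CurveResult",
    "ICCResult",
    "RankCorrelations",
    "BlandAltman",
    "SummaryStats",
    "AgreementReport",
    "LETTERS",
    "binary_confusion",
    "diagnostic_metrics",
    "roc_curve_auc",
    "precision_recall",
    "cohen_kappa",
    "weighted_kappa",
    "icc3k",
    "rank_correlations",
    "bland_altman",
    "tail_agreement",
    "ordinal_confusion",
    "summary_stats",
    "full_report",
]

#: Ordinal grade categories, best to worst. "F" is accepted on input as an
#: alias for the lowest band.
LETTERS = ("A", "B", "C", "D", "E")


@dataclass
class PairedScores:
    """Per-subject scores from the two graders, on the 0–100 scale."""

    subject_ids: list
    panel: np.ndarray
    software: np.ndarray

    def __post_init__(self) -> None:
        self.panel = np.asarray(self.panel, dtype=float)
        self.software = np.asarray(self.software, dtype=float)
        self.subject_ids = list(self.subject_ids)
        n = len(self.subject_ids)
        if len(self.panel) != n or len(self.software) != n:
            raise ValueError("subject_ids, panel and software must have equal length")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        for name, arr in (("panel", self.panel), ("software", self.software)):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite {name} score")
            if ((arr < 0) | (arr > 100)).any():
                raise ValueError(f"{name} scores must lie in [0, 100]")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedScores":
        df = pd.read_csv(path)
        missing = {"subject_id", "panel", "software"} - set(df.columns)
        if missing:
            raise ValueError(f"scores CSV missing column(s): {sorted(missing)}")
        bad = df.index[df[["panel", "software"]].isna().any(axis=1)]
        if len(bad):
            raise ValueError(f"scores CSV has missing values at data row {bad[0] + 1}")
        return cls(df["subject_id"].tolist(), df["panel"].to_numpy(), df["software"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"subject_id": self.subject_ids, "panel": self.panel, "software": self.software}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BinaryConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class OrdinalConfusion:
    """5×5 grade counts; rows = panel letters, columns = software letters."""

    matrix: np.ndarray
    letters: tuple = LETTERS

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.letters), columns=list(self.letters))


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


@dataclass
class CurveResult:
    """ROC or PR curve: x/y points, thresholds and area."""

    x: np.ndarray
    y: np.ndarray
    thresholds: np.ndarray
    area: float
    optimal_threshold: float | None = None


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class RankCorrelations:
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    median: float
    mode: float
    sd: float
    variance: float
    minimum: float
    maximum: float
    range: float
    q1: float
    q3: float
    iqr: float


def binary_confusion(scores: PairedScores, cutoff: float = DEFAULT_CUTOFF) -> BinaryConfusion:
    """2×2 pass/fail table: panel is truth, software the prediction, and the
    positive class is "pass" (score >= cutoff)."""
    truth = scores.panel >= cutoff
    pred = scores.software >= cutoff
    return BinaryConfusion(
        tp=int(np.sum(truth & pred)),
        fp=int(np.sum(~truth & pred)),
        fn=int(np.sum(truth & ~pred)),
        tn=int(np.sum(~truth & ~pred)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def diagnostic_metrics(c: BinaryConfusion) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV; NaN where a denominator is zero."""
    return DiagnosticMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def roc_curve_auc(scores: PairedScores, cutoff: float = DEFAULT_CUTOFF) -> CurveResult:
    """ROC of the software score against the panel pass/fail truth.

    AUC by the trapezoid rule, which for a score-threshold sweep equals the
    Mann–Whitney concordance probability with ties counted 1/2.
    """
    truth = (scores.panel >= cutoff).astype(int)
    if truth.min() == truth.max():
        return CurveResult(np.array([]), np.array([]), np.array([]), float("nan"))
    fpr, tpr, thr = _sk_roc_curve(truth, scores.software)
    return CurveResult(fpr, tpr, thr, float(_sk_auc(fpr, tpr)))


def precision_recall(scores: PairedScores, cutoff: float = DEFAULT_CUTOFF) -> CurveResult:
    """Precision–recall curve; area by the step-wise (average precision)
    estimator, plus the software threshold maximizing F1 (an "optimal
    cutoff" suggestion)."""
    truth = (scores.panel >= cutoff).astype(int)
    if truth.sum() == 0:
        return CurveResult(np.array([]), np.array([]), np.array([]), float("nan"))
    precision, recall, thr = _sk_pr_curve(truth, scores.software)
    # recall is decreasing; the step sum avoids the optimistic linear
    # interpolation between PR points
    area = float(-np.sum(np.diff(recall) * precision[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * precision[:-1] * recall[:-1] / (precision[:-1] + recall[:-1])
    f1 = np.nan_to_num(f1, nan=-1.0)
    best = int(np.argmax(f1))
    return CurveResult(recall, precision, thr, area, optimal_threshold=float(thr[best]))


def _normalize_letters(labels, categories) -> np.ndarray:
    """Map labels to category indices; 'F' aliases the lowest band."""
    cats = list(categories)
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        lab = str(lab).upper()
        if lab == "F" and "F" not in cats:
            lab = cats[-1]
        if lab not in cats:
            raise ValueError(f"unknown category {lab!r}")
        out[i] = cats.index(lab)
    return out


def cohen_kappa(labels_a, labels_b, categories=LETTERS) -> float:
    """Unweighted Cohen's kappa: (po − pe) / (1 − pe), expected agreement
    from the raters' marginal products."""
    a = _normalize_letters(labels_a, categories)
    b = _normalize_letters(labels_b, categories)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    k = len(categories)
    obs = np.zeros((k, k))
    np.add.at(obs, (a, b), 1.0)
    n = obs.sum()
    po = np.trace(obs) / n
    pe = float(obs.sum(axis=1) @ obs.sum(axis=0)) / n**2
    if np.isclose(pe, 1.0):
        return 1.0 if np.isclose(po, 1.0) else float("nan")
    return float((po - pe) / (1.0 - pe))


def weighted_kappa(labels_a, labels_b, scheme: str = "linear", categories=LETTERS) -> float:
    """Weighted kappa over ordered categories.

    Disagreement weights w_ij = |i−j|/(k−1) (linear) or ((i−j)/(k−1))²
    (quadratic); kappa = 1 − Σ w·observed / Σ w·expected. Categories are the
    full ordered grade space, so absent middle grades keep their spacing.
    """
    if scheme not in ("linear", "quadratic"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    a = _normalize_letters(labels_a, categories)
    b = _normalize_letters(labels_b, categories)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    k = len(categories)
    obs = np.zeros((k, k))
    np.add.at(obs, (a, b), 1.0)
    n = obs.sum()
    i, j = np.indices((k, k))
    w = np.abs(i - j) / (k - 1) if scheme == "linear" else ((i - j) / (k - 1)) ** 2
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    denom = float((w * expected).sum())
    if np.isclose(denom, 0.0):
        num = float((w * obs).sum())
        return 1.0 if np.isclose(num, 0.0) else float("nan")
    return float(1.0 - (w * obs).sum() / denom)


def icc3k(scores: PairedScores, confidence: float = 0.95) -> ICCResult:
    """ICC(3,k): two-way mixed effects, consistency, average of k=2 raters.

    From the two-way ANOVA decomposition, ICC(3,k) = (MS_subjects − MS_error)
    / MS_subjects; the CI comes from F-distribution bounds on
    F = MS_subjects / MS_error with (n−1, (n−1)(k−1)) degrees of freedom.
    """
    if scores.n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.column_stack([scores.panel, scores.software])
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_subj <= 0:
        return ICCResult(float("nan"), float("nan"), float("nan"), float("nan"))
    if ms_err == 0:
        return ICCResult(1.0, 1.0, 1.0, 0.0)
    value = (ms_subj - ms_err) / ms_subj
    f_obs = ms_subj / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    alpha = 1.0 - confidence
    f_upper = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_lower = stats.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = 1.0 - 1.0 / (f_obs / f_upper)
    ci_high = 1.0 - 1.0 / (f_obs * f_lower)
    p = float(stats.f.sf(f_obs, df1, df2))
    return ICCResult(float(value), float(ci_low), float(ci_high), p)


def rank_correlations(scores: PairedScores, seed: int = 0) -> RankCorrelations:
    """Spearman's rho (Pearson on mid-ranks) and Kendall's tau-b.

    p-values use the standard large-sample approximations; for n <= 10 they
    are replaced by seeded Monte-Carlo permutation p-values, where the
    asymptotic formulas are unreliable.
    """
    if scores.n < 3:
        raise ValueError("rank correlations need at least 3 subjects")
    x, y = scores.panel, scores.software
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RankCorrelations(float("nan"), float("nan"), float("nan"), float("nan"))
    rho, rho_p = stats.spearmanr(x, y)
    tau, tau_p = stats.kendalltau(x, y)  # tau-b (tie-corrected)
    if scores.n <= 10:
        rho_p = _permutation_p(x, y, lambda a, b: stats.spearmanr(a, b)[0], rho, seed)
        tau_p = _permutation_p(x, y, lambda a, b: stats.kendalltau(a, b)[0], tau, seed + 1)
    return RankCorrelations(float(rho), float(rho_p), float(tau), float(tau_p))


def _permutation_p(x, y, statistic, observed, seed, n_resamples: int = 4999) -> float:
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(len(y))
        if abs(statistic(x, y[perm])) >= abs(observed) - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)


def bland_altman(scores: PairedScores) -> BlandAltman:
    """Bias and 95% limits of agreement for software − panel differences:
    bias ± 1.96 × SD of the differences (sample SD, n−1)."""
    diffs = scores.software - scores.panel
    means = (scores.software + scores.panel) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, means, diffs)


def tail_agreement(scores: PairedScores, fraction: float, tail: str = "worst") -> float:
    """Percent overlap between the two graders' tail subject sets.

    The tail holds ceil(fraction·n) subjects — lowest scores for "worst",
    highest for "top" — selected per grader with ties broken by subject id;
    overlap is measured against the panel-defined tail.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if tail not in ("worst", "top"):
        raise ValueError(f"unknown tail {tail!r}")
    m = ceil(fraction * scores.n)
    ids = np.asarray(scores.subject_ids, dtype=object)

    def tail_set(values) -> set:
        keys = values if tail == "worst" else -values
        order = np.lexsort((ids.astype(str), keys))
        return set(ids[order[:m]])

    s_panel = tail_set(scores.panel)
    s_soft = tail_set(scores.software)
    return 100.0 * len(s_panel & s_soft) / len(s_panel)


def ordinal_confusion(scores: PairedScores) -> OrdinalConfusion:
    """5×5 letter-grade confusion matrix, rows = panel, columns = software."""
    a = [letter_grade(s) for s in scores.panel]
    b = [letter_grade(s) for s in scores.software]
    ai = _normalize_letters(a, LETTERS)
    bi = _normalize_letters(b, LETTERS)
    mat = np.zeros((len(LETTERS), len(LETTERS)), dtype=int)
    np.add.at(mat, (ai, bi), 1)
    return OrdinalConfusion(mat)


def summary_stats(values) -> SummaryStats:
    """Descriptives for one grader: mean, median, mode (smallest value on
    ties), sample SD/variance, min/max/range, and quartiles by linear
    interpolation between order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty score vector")
    uniq, counts = np.unique(v, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # np.unique sorts, so ties -> smallest
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    q1, q3 = (float(q) for q in np.percentile(v, [25, 75]))
    return SummaryStats(
        mean=float(v.mean()),
        median=float(np.median(v)),
        mode=mode,
        sd=sd,
        variance=sd**2,
        minimum=float(v.min()),
        maximum=float(v.max()),
        range=float(v.max() - v.min()),
        q1=q1,
        q3=q3,
        iqr=q3 - q1,
    )


@dataclass
class AgreementReport:
    """Everything the validation battery produces for one paired-score table."""

    n: int
    cutoff: float
    confusion: BinaryConfusion
    diagnostics: DiagnosticMetrics
    roc: CurveResult
    pr: CurveResult
    cohen_kappa: float
    linear_weighted_kappa: float
    quadratic_weighted_kappa: float
    icc: ICCResult
    ranks: RankCorrelations
    bland_altman: BlandAltman
    agreement_worst_5pct: float
    agreement_top_20pct: float
    grade_confusion: OrdinalConfusion
    panel_summary: SummaryStats
    software_summary: SummaryStats

    def to_flat_dict(self) -> dict[str, float]:
        d = {
            "n": self.n,
            "cutoff": self.cutoff,
            "sensitivity": self.diagnostics.sensitivity,
            "specificity": self.diagnostics.specificity,
            "ppv": self.diagnostics.ppv,
            "npv": self.diagnostics.npv,
            "auc_roc": self.roc.area,
            "auc_pr": self.pr.area,
            "cohen_kappa": self.cohen_kappa,
            "linear_weighted_kappa": self.linear_weighted_kappa,
            "quadratic_weighted_kappa": self.quadratic_weighted_kappa,
            "icc3k": self.icc.value,
            "icc3k_ci_low": self.icc.ci_low,
            "icc3k_ci_high": self.icc.ci_high,
            "spearman_rho": self.ranks.spearman_rho,
            "spearman_p": self.ranks.spearman_p,
            "kendall_tau": self.ranks.kendall_tau,
            "kendall_p": self.ranks.kendall_p,
            "bland_altman_bias": self.bland_altman.bias,
            "bland_altman_loa_low": self.bland_altman.loa_low,
            "bland_altman_loa_high": self.bland_altman.loa_high,
            "agreement_worst_5pct": self.agreement_worst_5pct,
            "agreement_top_20pct": self.agreement_top_20pct,
        }
        for grader, s in (("panel", self.panel_summary), ("software", self.software_summary)):
            for name in ("mean", "median", "mode", "sd", "variance", "minimum",
                         "maximum", "range", "q1", "q3", "iqr"):
                d[f"{grader}_{name}"] = getattr(s, name)
        return d


def full_report(scores: PairedScores, cutoff: float = DEFAULT_CUTOFF, seed: int = 0) -> AgreementReport:
    """Run the complete battery on one paired-score table."""
    confusion = binary_confusion(scores, cutoff)
    letters_panel = [letter_grade(s) for s in scores.panel]
    letters_soft = [letter_grade(s) for s in scores.software]
    return AgreementReport(
        n=scores.n,
        cutoff=cutoff,
        confusion=confusion,
        diagnostics=diagnostic_metrics(confusion),
        roc=roc_curve_auc(scores, cutoff),
        pr=precision_recall(scores, cutoff),
        cohen_kappa=cohen_kappa(letters_panel, letters_soft),
        linear_weighted_kappa=weighted_kappa(letters_panel, letters_soft, "linear"),
        quadratic_weighted_kappa=weighted_kappa(letters_panel, letters_soft, "quadratic"),
        icc=icc3k(scores),
        ranks=rank_correlations(scores, seed=seed),
        bland_altman=bland_altman(scores),
        agreement_worst_5pct=tail_agreement(scores, 0.05, "worst"),
        agreement_top_20pct=tail_agreement(scores, 0.20, "top"),
        grade_confusion=ordinal_confusion(scores),
        panel_summary=summary_stats(scores.panel),
        software_summary=summary_stats(scores.software),
    )
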