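"""Cohort-level statistics on per-subject mean RBC areas.

The workflow mirrors standard clinical-laboratory practice: per-group
normality is assessed with the Shapiro-Wilk test; two-group comparisons
dispatch on normality and variance homogeneity (pooled t-test when both
hold, Welch's unequal-variance t-test when only normality holds, two-sided
Wilcoxon rank-sum otherwise); area vs CBC-index association uses Pearson
when both variables look normal and Spearman otherwise; and diagnostic
value is summarized as ROC AUC for the area, for MCV, and for the fitted
case probability of a two-covariate logistic model combining them.

AUCs are computed with the Mann-Whitney rank identity (midranks for ties)
in the raw orientation "higher score -> case", so values below 0.5 are
reported as-is. The AUC p-value tests H0: AUC = 0.5 via the tie-corrected
normal approximation to U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .area import coefficient_of_variation  # noqa: F401  (re-exported for reports)

__all__ = [
    "ComparisonResult",
    "RocResult",
    "LogisticCombination",
    "shapiro_wilk",
    "compare_groups",
    "correlate",
    "roc_auc",
    "combined_predictor",
    "coefficient_of_variation",
]

ALPHA_NORMALITY = 0.05


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    iqr: float

    @classmethod
    def from_values(cls, v: np.ndarray) -> "GroupSummary":
        q75, q25 = np.percentile(v, [75, 25])
        return cls(
            n=len(v),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)),
            median=float(np.median(v)),
            iqr=float(q75 - q25),
        )


@dataclass
class ComparisonResult:
    test_used: str  # "t_test" | "welch_t" | "rank_sum"
    statistic: float
    p_value: float
    summary_x: GroupSummary
    summary_y: GroupSummary
    shapiro_p_x: float
    shapiro_p_y: float
    levene_p: float | None


@dataclass
class RocResult:
    marker: str
    auc: float
    p_value: float
    n_cases: int
    n_controls: int


@dataclass
class LogisticCombination:
    """Fitted two-marker logistic model: case probabilities and diagnostics."""

    probabilities: np.ndarray
    coefficients: np.ndarray
    separated: bool = False


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value; requires 3 <= n <= 5000."""
    v = np.asarray(values, float)
    if len(v) < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {len(v)}")
    if len(v) > 5000:
        raise ValueError(f"Shapiro-Wilk is defined for n <= 5000, got {len(v)}")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant data")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def compare_groups(x, y, alpha_normality: float = ALPHA_NORMALITY) -> ComparisonResult:
    """Two-group comparison with normality/variance dispatch.

    Both groups Shapiro-Wilk p > alpha and Levene p > alpha: pooled
    independent-sample t-test. Both normal but variances unequal: Welch's
    t-test. Otherwise: two-sided Wilcoxon rank-sum (Mann-Whitney U, normal
    approximation with tie correction).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(f"each group needs n >= 3, got {len(x)} and {len(y)}")
    try:
        _, p_x = shapiro_wilk(x)
        _, p_y = shapiro_wilk(y)
    except ValueError:
        # constant group: normality cannot hold
        p_x = p_y = 0.0
    both_normal = p_x > alpha_normality and p_y > alpha_normality

    levene_p: float | None = None
    if both_normal:
        _, levene_p = stats.levene(x, y)
        levene_p = float(levene_p)
        if levene_p > alpha_normality:
            stat, p = stats.ttest_ind(x, y, equal_var=True)
            test = "t_test"
        else:
            stat, p = stats.ttest_ind(x, y, equal_var=False)
            test = "welch_t"
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        test = "rank_sum"
    return ComparisonResult(
        test_used=test,
        statistic=float(stat),
        p_value=float(p),
        summary_x=GroupSummary.from_values(x),
        summary_y=GroupSummary.from_values(y),
        shapiro_p_x=float(p_x),
        shapiro_p_y=float(p_y),
        levene_p=levene_p,
    )


def correlate(x, y, alpha_normality: float = ALPHA_NORMALITY) -> tuple[str, float, float]:
    """Pearson when both variables pass Shapiro-Wilk, else Spearman.

    Returns ``(method, coefficient, two_sided_p)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError(f"paired samples differ in length: {len(x)} vs {len(y)}")
    if len(x) < 4:
        raise ValueError(f"correlation needs n >= 4, got {len(x)}")
    try:
        _, p_x = shapiro_wilk(x)
        _, p_y = shapiro_wilk(y)
        both_normal = p_x > alpha_normality and p_y > alpha_normality
    except ValueError:
        both_normal = False
    if both_normal:
        r, p = stats.pearsonr(x, y)
        return "pearson", float(r), float(p)
    r, p = stats.spearmanr(x, y)
    return "spearman", float(r), float(p)


def _as_case_indicator(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "bi":
        return lab.astype(bool)
    ind = np.zeros(len(lab), dtype=bool)
    for i, v in enumerate(lab):
        s = str(v).lower()
        if s == "case":
            ind[i] = True
        elif s == "control":
            ind[i] = False
        else:
            raise ValueError(f"label {v!r} is neither 'case' nor 'control'")
    return ind


def roc_auc(scores, labels, marker: str = "score") -> RocResult:
    """ROC AUC by the Mann-Whitney rank identity, ties as midranks.

    Orientation is "higher score -> case" and is not flipped, so an AUC
    below 0.5 indicates cases scoring lower than controls. The p-value is
    for H0: AUC = 0.5 using the tie-corrected normal approximation.
    """
    scores = np.asarray(scores, float)
    cases = _as_case_indicator(labels)
    n1 = int(cases.sum())
    n0 = int(len(cases) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both cases and controls must be present")
    ranks = stats.rankdata(scores)
    u = float(ranks[cases].sum() - n1 * (n1 + 1) / 2.0)
    auc = u / (n1 * n0)
    # tie-corrected variance of U under H0
    n = n1 + n0
    _, counts = np.unique(scores, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        p = 1.0
    else:
        z = (u - n1 * n0 / 2.0) / np.sqrt(var_u)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return RocResult(marker=marker, auc=float(auc), p_value=p, n_cases=n1, n_controls=n0)


def combined_predictor(area, mcv, labels) -> LogisticCombination:
    """Two-covariate logistic model: fitted case probabilities.

    Fit by unpenalized maximum likelihood. Under perfect separation the
    MLE diverges; the fit is then redone without the separation guard
    (coefficients are unstable but the probability ordering — all that the
    ROC uses — is the separating one) and flagged.
    """
    area = np.asarray(area, float)
    mcv = np.asarray(mcv, float)
    cases = _as_case_indicator(labels)
    if len(area) != len(mcv) or len(area) != len(cases):
        raise ValueError("area, mcv and labels must have equal length")
    if cases.all() or not cases.any():
        raise ValueError("both cases and controls must be present")
    X = sm.add_constant(np.column_stack([area, mcv]))
    model = sm.Logit(cases.astype(float), X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            # near-separated fits warn about convergence and overflow in
            # exp(); the predicted probability ordering is still well defined
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(disp=0)
        separated = False
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        model.raise_on_perfect_prediction = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, method="lbfgs", maxiter=200)
        separated = True
    return LogisticCombination(
        probabilities=np.asarray(res.predict(X)),
        coefficients=np.asarray(res.params),
        separated=separated,
    )
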