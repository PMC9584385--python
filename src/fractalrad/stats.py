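"""Group comparisons, logistic modelling with backward LR elimination,
ROC analysis, and interrater agreement.

The pipeline mirrors a conventional two-group radiogenomic analysis:

1. normality-routed comparisons (Shapiro–Wilk per group at α=0.05, then Welch
   t-test or Mann–Whitney U) for continuous variables; chi-square with
   continuity correction or Fisher's exact (any expected cell < 5) for 2×2
   tables;
2. univariable logistic screens (Wald P < 0.05) feeding a multivariable model
   reduced by backward elimination on likelihood-ratio tests (drop the worst
   term while its LR P ≥ 0.05), with VIF collinearity reporting and explicit
   detection of complete/quasi-complete separation — separated terms are
   flagged and never reported with a finite odds ratio;
3. ROC analysis: rank-based AUC (identical to the normalised Mann–Whitney U
   statistic), stratified percentile-bootstrap CI, and the Youden-optimal
   operating point;
4. Cohen's kappa for categorical ratings and ICC(2,1) (two-way random
   effects, absolute agreement, single measurement) for continuous ones.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import cohen_kappa_score

from .errors import DegenerateDataError, FitError, ParameterError, UndefinedAgreementError

__all__ = [
    "TestResult",
    "LogisticModel",
    "RocResult",
    "AgreementResult",
    "compare_continuous",
    "compare_categorical",
    "fit_logistic",
    "compute_vif",
    "backward_eliminate",
    "BackwardEliminationLogit",
    "roc_analysis",
    "cohen_kappa",
    "icc_two_way",
]


@dataclasses.dataclass
class TestResult:
    variable: str
    test_used: str  # {t-test, mann-whitney, chi-square, fisher}
    statistic: float
    p_value: float
    normality_p: tuple[float, float] | None = None


@dataclasses.dataclass
class LogisticModel:
    """Fitted logistic regression summary (possibly after elimination)."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]  # includes "const"
    odds_ratios: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    log_likelihood: float
    vif: dict[str, float]
    separation_flags: dict[str, str | None]
    converged: bool
    elimination_trace: tuple[tuple[str, float], ...] = ()
    univariable: dict[str, "LogisticModel"] = dataclasses.field(default_factory=dict)
    n_obs: int = 0

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.coefficients.get("const", 0.0))
        for t in self.terms:
            eta = eta + self.coefficients[t] * np.asarray(X[t], dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclasses.dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_boot: int = 0


@dataclasses.dataclass
class AgreementResult:
    measure: str  # {kappa, icc}
    value: float
    ci: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# group comparisons


def compare_continuous(
    x_group0: Sequence[float],
    x_group1: Sequence[float],
    alpha_normality: float = 0.05,
    variable: str = "",
) -> TestResult:
    """Welch t-test or Mann–Whitney U, routed by per-group Shapiro–Wilk.

    Both groups normal at ``alpha_normality`` → two-sided Welch t-test;
    otherwise two-sided Mann–Whitney U (exact when min(n) ≤ 20 and there are
    no ties, normal approximation with tie correction otherwise). A group
    with zero variance fails the normality route by definition.
    """
    x0 = np.asarray(x_group0, dtype=float)
    x1 = np.asarray(x_group1, dtype=float)
    if len(x0) < 3 or len(x1) < 3:
        raise ParameterError("each group needs n >= 3")
    if x0.std() == 0 and x1.std() == 0:
        raise DegenerateDataError(f"{variable}: constant in both groups")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # constant: certainly not normal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(sps.shapiro(x).pvalue)

    p_norm = (_shapiro_p(x0), _shapiro_p(x1))
    if min(p_norm) >= alpha_normality:
        stat, p = sps.ttest_ind(x0, x1, equal_var=False)
        return TestResult(variable, "t-test", float(stat), float(p), p_norm)
    ties = len(np.unique(np.concatenate([x0, x1]))) < len(x0) + len(x1)
    method = "exact" if (min(len(x0), len(x1)) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
    return TestResult(variable, "mann-whitney", float(res.statistic), float(res.pvalue), p_norm)


def compare_categorical(table: Sequence[Sequence[int]], variable: str = "") -> TestResult:
    """Chi-square (with continuity correction) or Fisher's exact on a 2×2 table.

    Fisher's exact two-sided test is used whenever any expected count is
    below 5, the standard small-sample rule.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ParameterError(f"{variable}: need a 2x2 table of non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateDataError(f"{variable}: zero margin in 2x2 table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        res = sps.fisher_exact(t.astype(int), alternative="two-sided")
        return TestResult(variable, "fisher", float(res.statistic), float(res.pvalue))
    chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
    return TestResult(variable, "chi-square", float(chi2), float(p))


# ---------------------------------------------------------------------------
# logistic modelling


def _separation_type(x: np.ndarray, y: np.ndarray) -> str | None:
    """Detect monotone (complete) or quasi-complete separation by one term."""
    x0, x1 = x[y == 0], x[y == 1]
    if len(x0) == 0 or len(x1) == 0:
        return "complete"
    if x0.max() < x1.min() or x1.max() < x0.min():
        return "complete"
    values = np.unique(x)
    if len(values) <= 2:
        # binary predictor: any empty cell of the 2x2 with the outcome makes
        # the MLE for this coefficient diverge (quasi-complete separation)
        for v in values:
            for cls, xg in ((0, x0), (1, x1)):
                if not np.any(xg == v):
                    return "quasi"
    else:
        if x0.max() == x1.min() or x1.max() == x0.min():
            return "quasi"
    return None


def fit_logistic(
    cohort: pd.DataFrame,
    outcome: str | np.ndarray,
    terms: Sequence[str],
) -> LogisticModel:
    """Maximum-likelihood logistic regression with separation flagging.

    ``outcome`` is a column name or an array; it must be binary with both
    classes present. Newton-type MLE via IRLS; Wald CIs on the odds-ratio
    scale. Terms inducing complete or quasi-complete separation are flagged
    and reported with NaN coefficients and no finite CI, because their MLE
    diverges. VIF is computed on the term design matrix when there are at
    least two terms.
    """
    y = np.asarray(cohort[outcome] if isinstance(outcome, str) else outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ParameterError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("outcome has a single class")
    terms = list(terms)
    if len(y) <= len(terms) + 1:
        raise ParameterError(f"n={len(y)} too small for {len(terms)} terms")
    X = cohort[terms].astype(float) if terms else pd.DataFrame(index=np.arange(len(y)))
    sep = {t: _separation_type(X[t].to_numpy(), y) for t in terms}
    design = sm.add_constant(X, has_constant="add")

    names = list(design.columns)
    coef = {n: np.nan for n in names}
    ors = {n: np.nan for n in names}
    ci = {n: (np.nan, np.nan) for n in names}
    pvals = {n: np.nan for n in names}
    llf = np.nan
    converged = False
    if not any(v == "complete" for v in sep.values()):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            llf = float(res.llf)
            conf = res.conf_int()
            np_err = np.seterr(over="ignore")  # huge Wald bounds overflow to inf harmlessly
            for n in names:
                coef[n] = float(res.params[n])
                ors[n] = float(np.exp(res.params[n]))
                ci[n] = (float(np.exp(conf.loc[n, 0])), float(np.exp(conf.loc[n, 1])))
                pvals[n] = float(res.pvalues[n])
            np.seterr(**np_err)
        except Exception as exc:
            if not any(sep.values()):
                raise FitError(f"logistic fit failed for terms {terms}: {exc}") from exc
    # separated terms: estimates diverge, report nothing finite
    for t, flag in sep.items():
        if flag is not None:
            coef[t] = np.nan
            ors[t] = np.nan
            ci[t] = (np.nan, np.inf)
            pvals[t] = np.nan
    return LogisticModel(
        terms=tuple(terms),
        coefficients=coef,
        odds_ratios={k: v for k, v in ors.items() if k != "const"},
        or_ci={k: v for k, v in ci.items() if k != "const"},
        p_values=pvals,
        log_likelihood=llf,
        vif=compute_vif(cohort, terms) if len(terms) >= 2 else {t: 1.0 for t in terms},
        separation_flags=sep,
        converged=converged,
        n_obs=len(y),
    )


def compute_vif(cohort: pd.DataFrame, terms: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors of the term design matrix (with intercept).

    Exactly collinear terms (e.g. duplicated columns) yield infinite VIF.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    X = sm.add_constant(cohort[list(terms)].astype(float), has_constant="add")
    out = {}
    with warnings.catch_warnings(), np.errstate(divide="ignore"):
        warnings.simplefilter("ignore")
        for i, t in enumerate(terms):
            out[t] = float(variance_inflation_factor(X.values, i + 1))
    return out


def backward_eliminate(
    cohort: pd.DataFrame,
    outcome: str,
    candidate_terms: Sequence[str],
    p_enter: float = 0.05,
    p_stay: float = 0.05,
    vif_threshold: float = 10.0,
) -> LogisticModel:
    """Univariable screen then backward elimination by likelihood ratio.

    Candidates are the terms with univariable Wald P < ``p_enter``; terms
    whose univariable fit is separated are excluded (recorded with a NaN
    trace entry). From the full candidate model, the term with the largest
    likelihood-ratio P is dropped while that P ≥ ``p_stay``. VIF is computed
    once on the candidate design matrix and reported on the result; terms
    with VIF ≥ ``vif_threshold`` are kept but flagged via the ``vif`` map.
    An empty final model (intercept only) is a valid result, not an error.
    """
    candidate_terms = list(candidate_terms)
    if not candidate_terms:
        raise ParameterError("candidate_terms must be nonempty")
    uni: dict[str, LogisticModel] = {}
    selected: list[str] = []
    for t in candidate_terms:
        m = fit_logistic(cohort, outcome, [t])
        uni[t] = m
        p = m.p_values.get(t, np.nan)
        if m.separation_flags.get(t) is None and np.isfinite(p) and p < p_enter:
            selected.append(t)
    vif = compute_vif(cohort, selected) if len(selected) >= 2 else {t: 1.0 for t in selected}
    trace: list[tuple[str, float]] = []
    terms = list(selected)

    def _try_fit(ts):
        try:
            m = fit_logistic(cohort, outcome, ts)
        except FitError:
            return None
        return m if np.isfinite(m.log_likelihood) else None

    final = None
    while terms:
        full = _try_fit(terms)
        if full is None:
            # model too rich for the data (singular Hessian / joint
            # separation): shed the weakest candidate by univariable p
            weakest = max(terms, key=lambda t: _finite_or(uni[t].p_values.get(t), 1.0))
            terms.remove(weakest)
            trace.append((weakest, float("nan")))
            continue
        lr_p = {}
        for t in terms:
            reduced = _try_fit([u for u in terms if u != t])
            if reduced is None:
                continue
            lr = max(2.0 * (full.log_likelihood - reduced.log_likelihood), 0.0)
            lr_p[t] = float(sps.chi2.sf(lr, df=1))
        if not lr_p:
            final = full
            break
        worst = max(lr_p, key=lambda t: lr_p[t])
        if lr_p[worst] >= p_stay:
            terms.remove(worst)
            trace.append((worst, lr_p[worst]))
        else:
            final = full
            break
    if final is None:
        final = fit_logistic(cohort, outcome, terms)
    final.elimination_trace = tuple(trace)
    final.univariable = uni
    final.vif = vif
    return final


def _finite_or(value, default):
    return float(value) if value is not None and np.isfinite(value) else default


class BackwardEliminationLogit(BaseEstimator, ClassifierMixin):
    """sklearn-style classifier wrapping the screen-and-eliminate procedure.

    ``fit(X, y)`` expects a DataFrame of candidate predictors and a binary
    outcome; fitted attributes expose the selected terms, coefficients and
    the elimination trace, and ``predict_proba`` scores new cohorts with the
    final reduced model.
    """

    def __init__(self, p_enter: float = 0.05, p_stay: float = 0.05, vif_threshold: float = 10.0):
        self.p_enter = p_enter
        self.p_stay = p_stay
        self.vif_threshold = vif_threshold

    def fit(self, X: pd.DataFrame, y) -> "BackwardEliminationLogit":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        self.model_ = backward_eliminate(
            X.assign(__outcome__=y),
            "__outcome__",
            [c for c in X.columns],
            p_enter=self.p_enter,
            p_stay=self.p_stay,
            vif_threshold=self.vif_threshold,
        )
        self.classes_ = np.array([0.0, 1.0])
        self.selected_terms_ = list(self.model_.terms)
        self.coef_ = np.array([[self.model_.coefficients[t] for t in self.model_.terms]])
        self.intercept_ = np.array([self.model_.coefficients.get("const", 0.0)])
        self.elimination_trace_ = self.model_.elimination_trace
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = self.model_.predict_proba(pd.DataFrame(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(float)


# ---------------------------------------------------------------------------
# ROC


def _auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal/rank AUC with midrank tie handling = U/(n0·n1)."""
    ranks = sps.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """AUC with stratified percentile-bootstrap CI and the Youden point.

    The AUC is the rank statistic (equal to the Mann–Whitney U divided by
    n₀·n₁, midranks for ties). The operating point maximises Youden's
    J = sensitivity + specificity − 1 over thresholds of the form
    "positive if score ≥ t" for observed scores t; ties on J resolve to the
    highest such threshold. Bootstrap resampling is stratified by class.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
        raise DegenerateDataError("labels must contain both classes 0 and 1")
    auc = _auc_rank(scores, y)

    thresholds = np.unique(scores)[::-1]
    pos, neg = scores[y == 1], scores[y == 0]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first index = highest threshold on ties
    thr = float(thresholds[best])
    acc = float(((scores >= thr) == (y == 1)).mean())

    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        i1 = rng.choice(idx1, size=len(idx1), replace=True)
        i0 = rng.choice(idx0, size=len(idx0), replace=True)
        s = np.concatenate([scores[i1], scores[i0]])
        yy = np.concatenate([np.ones(len(i1)), np.zeros(len(i0))])
        boots[b] = _auc_rank(s, yy)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return RocResult(
        auc=auc,
        auc_ci=ci,
        threshold=thr,
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        accuracy=acc,
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# interrater agreement


def cohen_kappa(ratings_a: Sequence, ratings_b: Sequence) -> AgreementResult:
    """Cohen's kappa with marginal-product chance agreement and a normal CI."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if len(a) != len(b) or len(a) < 2:
        raise ParameterError("ratings must have equal length >= 2")
    cats = np.union1d(np.unique(a), np.unique(b))
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        raise UndefinedAgreementError("both raters constant: chance agreement is 1")
    kappa = float(cohen_kappa_score(a, b))
    p_o = float((a == b).mean())
    se = np.sqrt(p_o * (1 - p_o) / (len(a) * (1 - p_e) ** 2))
    ci = (max(kappa - 1.96 * se, -1.0), min(kappa + 1.96 * se, 1.0))
    return AgreementResult(measure="kappa", value=kappa, ci=ci)


def icc_two_way(ratings: np.ndarray | pd.DataFrame) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a subjects × 2-raters matrix with no missing cells.
    """
    import pingouin as pg

    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2 or m.shape[0] < 5:
        raise ParameterError("need a (subjects >= 5) x (2 raters) matrix")
    if np.isnan(m).any():
        raise ParameterError("missing cells are not supported")
    if np.allclose(m.mean(axis=1), m.mean(axis=1)[0]):
        raise UndefinedAgreementError("zero between-subject variance")
    n = m.shape[0]
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "rater": np.tile(["A", "B"], n),
            "score": m.reshape(-1),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    icc = icc.set_index("Type")
    # absolute-agreement single-measure row; label differs across versions
    label = "ICC(A,1)" if "ICC(A,1)" in icc.index else "ICC2"
    row = icc.loc[label]
    ci_col = next(c for c in ("CI95%", "CI95") if c in icc.columns)
    ci = tuple(float(v) for v in row[ci_col])
    return AgreementResult(measure="icc", value=float(row["ICC"]), ci=ci)


def comparison_table(
    cohort: pd.DataFrame,
    group_col: str = "group",
    positive_group: str = "mutant",
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
    alpha_normality: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group comparison summary (one row per variable)."""
    g = cohort[group_col] == positive_group
    rows = []
    for var in continuous:
        r = compare_continuous(
            cohort.loc[~g, var], cohort.loc[g, var], alpha_normality, variable=var
        )
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "wildtype_mean": float(cohort.loc[~g, var].mean()),
                "wildtype_sd": float(cohort.loc[~g, var].std()),
                "mutant_mean": float(cohort.loc[g, var].mean()),
                "mutant_sd": float(cohort.loc[g, var].std()),
                "test_used": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
            }
        )
    for var in binary:
        x = cohort[var].astype(int)
        table = [
            [int(((x == 0) & ~g).sum()), int(((x == 1) & ~g).sum())],
            [int(((x == 0) & g).sum()), int(((x == 1) & g).sum())],
        ]
        r = compare_categorical(table, variable=var)
        rows.append(
            {
                "variable": var,
                "type": "binary",
                "wildtype_mean": float(x[~g].mean()),
                "wildtype_sd": np.nan,
                "mutant_mean": float(x[g].mean()),
                "mutant_sd": np.nan,
                "test_used": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)
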