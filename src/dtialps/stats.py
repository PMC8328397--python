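"""Association statistics for ALPS cohort tables.

Mirrors the analysis plan of ROI-based glymphatic studies: univariate
screens (Pearson for continuous predictors, two-sample t for binaries,
one-way ANOVA with Bonferroni post hoc for the ordinal venous score),
then a multiple linear regression on standardized variables with
forward/backward selection, variance-inflation factors, residual
diagnostics, and Cohen's kappa for inter-rater agreement.

The regression machinery is exposed as scikit-learn-compatible estimators
(:class:`StandardizedOLS`, :class:`StepwiseSelector`) so it composes with
sklearn pipelines and model selection; the module-level functions are thin
wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "StandardizedOLS",
    "StepwiseSelector",
    "UnivariateResult",
    "ModelFit",
    "univariate_screen",
    "bonferroni_posthoc",
    "fit_standardized_ols",
    "vif",
    "stepwise_select",
    "cohens_kappa",
    "residual_diagnostics",
    "CONTINUOUS_PREDICTORS",
    "BINARY_PREDICTORS",
    "DEFAULT_CANDIDATES",
]

CONTINUOUS_PREDICTORS = (
    "age",
    "psqi",
    "icv_ml",
    "brain_to_icv",
    "wmh_norm",
    "bgpvs_score",
    "wmpvs_score",
    "n_lacunes",
    "n_microbleeds",
    "wmh_overlap_mm3",
)
BINARY_PREDICTORS = ("sex", "hypertension", "hyperlipemia", "diabetes", "smoker")
ANOVA_PREDICTORS = ("dmv_score",)

#: The full candidate list entered into selection.
DEFAULT_CANDIDATES = CONTINUOUS_PREDICTORS + BINARY_PREDICTORS + ANOVA_PREDICTORS


@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    kind: str  # pearson_r | t | F
    statistic: float
    p_value: float
    group_means: dict | None = None
    posthoc: dict | None = None


@dataclass
class ModelFit:
    """Result of a (possibly selected) standardized linear model."""

    variables: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    adjusted_r2: float
    r2: float
    vif: dict[str, float]
    n_obs: int
    selection_trace: list[tuple[str, str, float]] = field(default_factory=list)
    forward_set: list[str] | None = None
    backward_set: list[str] | None = None
    directions_disagree: bool = False
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "std_beta": [self.coefficients[v] for v in self.variables],
                "p_value": [self.p_values[v] for v in self.variables],
                "vif": [self.vif.get(v, np.nan) for v in self.variables],
            }
        )


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(names))


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant predictor(s): {constant}")
    return (frame - frame.mean()) / sd


class StandardizedOLS(RegressorMixin, BaseEstimator):
    """Ordinary least squares on z-scored outcome and predictors.

    Both sides are standardized by sample mean and SD (``ddof=1``), so the
    fitted slopes are standardized betas — with one predictor the beta
    equals the Pearson correlation.  The intercept is zero by construction;
    p-values, R-squared and adjusted R-squared are identical to the
    unstandardized fit's because standardization is affine.

    Attributes (after ``fit``): ``coef_``, ``pvalues_``, ``rsquared_``,
    ``adj_rsquared_``, ``vif_``, ``feature_names_in_``, ``residuals_``
    (on the original outcome scale), ``fitted_``.
    """

    def __init__(self, compute_vif: bool = True):
        self.compute_vif = compute_vif

    def fit(self, X, y):
        frame = _as_frame(X)
        y = np.asarray(y, dtype=float)
        n, p = frame.shape
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
        if not np.isfinite(frame.to_numpy()).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in design or outcome")
        if np.std(y, ddof=1) == 0:
            raise ValueError("constant outcome")
        Xz = _zscore(frame)
        rank = np.linalg.matrix_rank(Xz.to_numpy())
        if rank < p:
            corr = np.corrcoef(Xz.to_numpy(), rowvar=False)
            dep = [
                (frame.columns[i], frame.columns[j])
                for i in range(p)
                for j in range(i + 1, p)
                if abs(corr[i, j]) > 1 - 1e-10
            ]
            raise ValueError(f"perfectly collinear predictors: {dep or list(frame.columns)}")
        yz = (y - y.mean()) / np.std(y, ddof=1)
        # fit with an explicit (numerically ~0) intercept so p-values and
        # degrees of freedom match ordinary regression software
        res = sm.OLS(yz, sm.add_constant(Xz, has_constant="add")).fit()
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = p
        self.coef_ = res.params.iloc[1:].to_numpy()
        self.pvalues_ = res.pvalues.iloc[1:].to_numpy()
        self.rsquared_ = float(res.rsquared)
        self.adj_rsquared_ = float(res.rsquared_adj)
        self.fitted_ = y.mean() + np.std(y, ddof=1) * res.fittedvalues.to_numpy()
        self.residuals_ = y - self.fitted_
        self._ymean = float(y.mean())
        self._ysd = float(np.std(y, ddof=1))
        self._xmean = frame.mean().to_numpy()
        self._xsd = frame.std(ddof=1).to_numpy()
        if self.compute_vif and p >= 2:
            design = Xz.to_numpy()
            self.vif_ = np.array(
                [variance_inflation_factor(design, j) for j in range(p)]
            )
        else:
            self.vif_ = np.ones(p)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        frame = _as_frame(X, feature_names=list(self.feature_names_in_))
        Xz = (frame[list(self.feature_names_in_)].to_numpy() - self._xmean) / self._xsd
        return self._ymean + self._ysd * (Xz @ self.coef_)

    def to_model_fit(self) -> ModelFit:
        check_is_fitted(self, "coef_")
        names = list(self.feature_names_in_)
        return ModelFit(
            variables=names,
            coefficients=dict(zip(names, map(float, self.coef_))),
            p_values=dict(zip(names, map(float, self.pvalues_))),
            adjusted_r2=self.adj_rsquared_,
            r2=self.rsquared_,
            vif=dict(zip(names, map(float, self.vif_))),
            n_obs=len(self.residuals_),
            residuals=self.residuals_,
            fitted=self.fitted_,
        )


def fit_standardized_ols(table: pd.DataFrame, outcome: str, predictors) -> ModelFit:
    """Standardized OLS of ``outcome`` on ``predictors`` (function surface
    over :class:`StandardizedOLS`)."""
    est = StandardizedOLS().fit(table[list(predictors)], table[outcome].to_numpy())
    return est.to_model_fit()


def vif(table: pd.DataFrame, predictors) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1/(1 - R2_j) of predictor j
    regressed on the others."""
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    Xz = _zscore(table[predictors])
    if np.linalg.matrix_rank(Xz.to_numpy()) < len(predictors):
        raise ValueError("perfect collinearity: VIF is infinite")
    design = Xz.to_numpy()
    return {
        name: float(variance_inflation_factor(design, j))
        for j, name in enumerate(predictors)
    }


# --------------------------------------------------------------------------
# Univariate screen

def univariate_screen(
    table: pd.DataFrame,
    outcome: str = "alps_mean",
    continuous=CONTINUOUS_PREDICTORS,
    binary=BINARY_PREDICTORS,
    anova=ANOVA_PREDICTORS,
    equal_var: bool = True,
) -> list[UnivariateResult]:
    """Per-predictor association with the outcome.

    Pearson correlation for continuous predictors, two-sided equal-variance
    t-test for binaries, one-way ANOVA (with Bonferroni-corrected pairwise
    post hoc) for multi-level ordinal scores.  Binaries with a single level
    present are skipped.  No multiplicity correction is applied across the
    screen itself.
    """
    y = table[outcome].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(y) == 0:
        raise ValueError("constant outcome")
    results: list[UnivariateResult] = []
    for var in continuous:
        if var not in table.columns:
            continue
        x = table[var].to_numpy(dtype=float)
        r, p = sps.pearsonr(x, y)
        results.append(UnivariateResult(var, "pearson_r", float(r), float(p)))
    for var in binary:
        if var not in table.columns:
            continue
        x = table[var].to_numpy()
        levels = np.unique(x)
        if len(levels) < 2:
            continue  # skipped with warning semantics: one level present
        g0, g1 = y[x == levels[0]], y[x == levels[1]]
        if g0.std() == 0 and g1.std() == 0 and g0.mean() == g1.mean():
            t, p = 0.0, 1.0  # identical degenerate groups: no evidence
        else:
            t, p = sps.ttest_ind(g1, g0, equal_var=equal_var)
        results.append(
            UnivariateResult(
                var, "t", float(t), float(p),
                group_means={int(levels[0]): float(g0.mean()), int(levels[1]): float(g1.mean())},
            )
        )
    for var in anova:
        if var not in table.columns:
            continue
        x = table[var].to_numpy()
        levels = [lv for lv in np.unique(x)]
        groups = [y[x == lv] for lv in levels]
        if any(len(g) == 0 for g in groups):
            raise ValueError(f"empty level in {var!r}")
        if len(groups) < 2:
            continue
        f, p = sps.f_oneway(*groups)
        post = bonferroni_posthoc(groups, labels=[int(lv) for lv in levels],
                                  equal_var=equal_var)
        results.append(
            UnivariateResult(
                var, "F", float(f), float(p),
                group_means={int(lv): float(g.mean()) for lv, g in zip(levels, groups)},
                posthoc=post,
            )
        )
    return results


def bonferroni_posthoc(groups, labels=None, equal_var: bool = True) -> dict:
    """Pairwise t-tests with Bonferroni correction (p * k(k-1)/2, capped at 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if labels is None:
        labels = list(range(len(groups)))
    n_comp = len(groups) * (len(groups) - 1) // 2
    out = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if np.std(groups[i]) == 0 and np.std(groups[j]) == 0 and (
                groups[i].mean() == groups[j].mean()
            ):
                p = 1.0
            else:
                _, p = sps.ttest_ind(groups[i], groups[j], equal_var=equal_var)
            out[(labels[i], labels[j])] = float(min(1.0, p * n_comp))
    return out


# --------------------------------------------------------------------------
# Stepwise selection

class StepwiseSelector(BaseEstimator):
    """Forward selection and backward elimination over candidate predictors.

    Forward: repeatedly add the candidate whose partial-F p-value (the
    t-test of its coefficient given the current model) is smallest, while
    below ``alpha_enter``.  Backward: start from the full model and drop the
    largest p-value while above ``alpha_remove``.  The final reported model
    is the forward set refit with :class:`StandardizedOLS`; when the two
    directions disagree a flag is raised.  ``bidirectional=True`` instead
    alternates removal steps into the forward pass (classic stepwise).

    Attributes: ``selected_``, ``forward_set_``, ``backward_set_``,
    ``directions_disagree_``, ``trace_``, ``model_`` (fitted
    :class:`StandardizedOLS`, or None when nothing enters).
    """

    def __init__(self, alpha_enter: float = 0.05, alpha_remove: float = 0.10,
                 bidirectional: bool = False):
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove
        self.bidirectional = bidirectional

    @staticmethod
    def _pvalues(frame: pd.DataFrame, y: np.ndarray, current: list[str]) -> pd.Series:
        Xz = _zscore(frame[current])
        yz = (y - y.mean()) / np.std(y, ddof=1)
        res = sm.OLS(yz, sm.add_constant(Xz, has_constant="add")).fit()
        return res.pvalues.iloc[1:]

    def fit(self, X, y, feature_names=None):
        if self.alpha_enter > self.alpha_remove:
            raise ValueError("alpha_enter must be <= alpha_remove")
        frame = _as_frame(X, feature_names)
        y = np.asarray(y, dtype=float)
        candidates = list(frame.columns)
        trace: list[tuple[str, str, float]] = []

        # forward
        selected: list[str] = []
        remaining = list(candidates)
        while remaining:
            best_var, best_p = None, None
            for var in remaining:
                pvals = self._pvalues(frame, y, selected + [var])
                p = float(pvals.loc[var])
                if best_p is None or p < best_p:
                    best_var, best_p = var, p
            if best_p is not None and best_p < self.alpha_enter:
                selected.append(best_var)
                remaining.remove(best_var)
                trace.append(("enter", best_var, best_p))
                if self.bidirectional and len(selected) > 1:
                    while len(selected) > 1:
                        pvals = self._pvalues(frame, y, selected)
                        worst = pvals.idxmax()
                        if float(pvals.loc[worst]) > self.alpha_remove:
                            selected.remove(worst)
                            remaining.append(worst)
                            trace.append(("remove", worst, float(pvals.loc[worst])))
                        else:
                            break
            else:
                break
        forward_set = list(selected)

        # backward, from the full model
        backward = list(candidates)
        while len(backward) > 0:
            pvals = self._pvalues(frame, y, backward)
            worst = pvals.idxmax()
            worst_p = float(pvals.loc[worst])
            if worst_p > self.alpha_remove:
                backward.remove(worst)
                trace.append(("backward-remove", worst, worst_p))
            else:
                break

        self.feature_names_in_ = np.asarray(candidates, dtype=object)
        self.n_features_in_ = len(candidates)
        self.forward_set_ = forward_set
        self.backward_set_ = backward
        self.directions_disagree_ = set(forward_set) != set(backward)
        self.trace_ = trace
        self.selected_ = list(forward_set)
        if self.selected_:
            self.model_ = StandardizedOLS().fit(frame[self.selected_], y)
        else:
            self.model_ = None
        return self

    def get_support(self):
        check_is_fitted(self, "selected_")
        return np.isin(self.feature_names_in_, self.selected_)

    def transform(self, X):
        check_is_fitted(self, "selected_")
        frame = _as_frame(X, feature_names=list(self.feature_names_in_))
        return frame[self.selected_]

    def to_model_fit(self) -> ModelFit:
        check_is_fitted(self, "selected_")
        if self.model_ is None:
            fit = ModelFit(
                variables=[], coefficients={}, p_values={}, adjusted_r2=np.nan,
                r2=np.nan, vif={}, n_obs=0,
            )
        else:
            fit = self.model_.to_model_fit()
        fit.selection_trace = self.trace_
        fit.forward_set = self.forward_set_
        fit.backward_set = self.backward_set_
        fit.directions_disagree = self.directions_disagree_
        return fit


def stepwise_select(
    table: pd.DataFrame,
    outcome: str,
    candidates=DEFAULT_CANDIDATES,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    bidirectional: bool = False,
) -> ModelFit:
    """Forward/backward variable selection (function surface over
    :class:`StepwiseSelector`).  An empty selection yields an empty
    :class:`ModelFit`, not an error."""
    candidates = [c for c in candidates if c in table.columns]
    sel = StepwiseSelector(alpha_enter, alpha_remove, bidirectional)
    sel.fit(table[candidates], table[outcome].to_numpy())
    return sel.to_model_fit()


# --------------------------------------------------------------------------
# Agreement and diagnostics

def cohens_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), chance agreement from the
    raters' marginal distributions.  Perfect agreement with p_e = 1 (both
    raters constant and equal) is defined as 1."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError(f"ratings must be equal-length 1-D, got {a.shape} vs {b.shape}")
    cats = np.unique(np.concatenate([a, b]))
    p_o = float(np.mean(a == b))
    pa = np.array([np.mean(a == c) for c in cats])
    pb = np.array([np.mean(b == c) for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class ResidualDiagnostics:
    normality_statistic: float
    normality_p: float
    normality_pass: bool
    het_slope: float
    het_p: float
    homoscedastic_pass: bool
    skipped: bool = False
    note: str = ""


def residual_diagnostics(fit: ModelFit, alpha: float = 0.05) -> ResidualDiagnostics:
    """Shapiro-Wilk residual normality plus a residual-vs-fitted
    heteroscedasticity check (slope of squared residuals on fitted values).

    A saturated model (residual degrees of freedom <= 1) skips the
    diagnostics with a note instead of producing meaningless statistics.
    """
    if fit.residuals is None or fit.fitted is None:
        raise ValueError("ModelFit carries no residuals (empty model?)")
    resid = np.asarray(fit.residuals, dtype=float)
    n_params = len(fit.variables) + 1
    if len(resid) - n_params <= 1:
        return ResidualDiagnostics(np.nan, np.nan, False, np.nan, np.nan, False,
                                   skipped=True, note="saturated model: diagnostics skipped")
    w, p_norm = sps.shapiro(resid)
    res = sm.OLS(resid**2, sm.add_constant(np.asarray(fit.fitted))).fit()
    slope = float(res.params[1])
    p_het = float(res.pvalues[1])
    return ResidualDiagnostics(
        normality_statistic=float(w),
        normality_p=float(p_norm),
        normality_pass=p_norm >= alpha,
        het_slope=slope,
        het_p=p_het,
        homoscedastic_pass=p_het >= alpha,
    )
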