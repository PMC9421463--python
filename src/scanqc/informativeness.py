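"""Which QC features carry information about visual quality judgments?

Three stages, mirroring a standard cohort QC analysis:

1. **Covariate screen** — one linear model per feature against site
   (categorical), age, sex, MMSE, amyloid and APOE status, with
   Bonferroni correction across every feature x covariate test. Features
   tied to biology rather than acquisition deserve caution as QC
   criteria.
2. **Proportional-odds ordinal regression** of the visual label
   (poor < moderate < good) on the QC features:
   P(Y <= k | x) = logistic(theta_k - x'beta). Exposed statsmodels-style
   as :class:`OrdinalQCModel` whose ``fit()`` returns
   :class:`OrdinalQCResults` (coefficients, odds ratios, Wald 95% CIs,
   p-values, log-likelihood, AIC, ``summary()``).
3. **Backward AIC elimination** — greedily drop the single feature whose
   removal lowers AIC most, until no removal lowers it; the reduced
   model is compared with the full one by a likelihood-ratio test.

Predictors are z-standardized internally for numerical stability; the
reported coefficients, odds ratios and CIs are transformed back to the
raw feature scale (an affine reparametrization, so fit quality, AIC and
p-values are unaffected).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .images import InputError
from .flagging import VISUAL_LABELS

logger = logging.getLogger(__name__)

SCREEN_COVARIATES = ("site", "age", "sex", "MMSE", "amyloid", "APOE")


class FitError(RuntimeError):
    """The ordinal likelihood optimization failed."""


class _FastOrderedLogit(OrderedModel):
    """OrderedModel (logit link) with an analytic score.

    The parent class differentiates the likelihood numerically, which
    dominates fit time; the proportional-odds gradient has a simple
    closed form. With parameters (beta, a) where theta_0 = a_0 and
    theta_j = theta_{j-1} + exp(a_j), and u_ij = theta_j - x_i'beta:

        dll_i/dbeta = -x_i (f(u_ij) - f(u_{i,j-1})) / P_i
        dll_i/dtheta_m = (f(u_ij) 1[m=j] - f(u_{i,j-1}) 1[m=j-1]) / P_i

    with P_i = F(u_ij) - F(u_{i,j-1}), f = F(1-F) for the logistic, and
    the chain rule dtheta_j/da_m = 1 (m=0) or exp(a_m) 1[j>=m].
    """

    def __init__(self, endog, exog, **kwargs):
        kwargs.setdefault("distr", "logit")
        super().__init__(endog, exog, **kwargs)

    def score(self, params):
        k = self.exog.shape[1]
        beta = params[:k]
        thresholds = self.transform_threshold_params(params)  # [-inf, t_0.., +inf]
        y = np.asarray(self.endog, dtype=int)
        xb = self.exog @ beta
        u_hi = thresholds[y + 1] - xb
        u_lo = thresholds[y] - xb

        def cdf(u):
            out = np.empty_like(u)
            finite = np.isfinite(u)
            out[finite] = 1.0 / (1.0 + np.exp(-u[finite]))
            out[~finite] = (u[~finite] > 0).astype(float)
            return out

        F_hi, F_lo = cdf(u_hi), cdf(u_lo)
        f_hi = F_hi * (1.0 - F_hi)
        f_lo = F_lo * (1.0 - F_lo)
        prob = np.maximum(F_hi - F_lo, 1e-300)

        g_beta = -self.exog.T @ ((f_hi - f_lo) / prob)
        n_thresh = len(thresholds) - 2
        g_theta = np.zeros(n_thresh)
        w_hi = f_hi / prob
        w_lo = f_lo / prob
        np.add.at(g_theta, np.clip(y, 0, n_thresh - 1),
                  np.where(y <= n_thresh - 1, w_hi, 0.0))
        np.add.at(g_theta, np.clip(y - 1, 0, n_thresh - 1),
                  np.where(y >= 1, -w_lo, 0.0))
        # chain rule to the increment parametrization
        g_a = np.empty(n_thresh)
        g_a[0] = g_theta.sum()
        for m in range(1, n_thresh):
            g_a[m] = g_theta[m:].sum() * np.exp(params[k + m])
        return np.concatenate([g_beta, g_a])


# ---------------------------------------------------------------------------
# Covariate screen


@dataclasses.dataclass
class ScreenResult:
    """Feature x covariate association tests with Bonferroni control.

    ``table`` columns: feature, covariate, statistic (F), p_raw, p_bonf,
    significant (at ``alpha`` after correction).
    """

    table: pd.DataFrame
    n_tests: int
    alpha: float = 0.05

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _screen_formula(feature: str, covariates: tuple[str, ...], df: pd.DataFrame) -> str:
    terms = []
    for cov in covariates:
        if cov == "site" or not pd.api.types.is_numeric_dtype(df[cov]):
            terms.append(f"C(Q('{cov}'))")
        else:
            terms.append(f"Q('{cov}')")
    return f"Q('{feature}') ~ " + " + ".join(terms)


def covariate_screen(cohort: pd.DataFrame, feature_cols: list[str],
                     covariates: tuple[str, ...] = SCREEN_COVARIATES,
                     alpha: float = 0.05) -> ScreenResult:
    """Fit one OLS model per feature on the six covariates and test each
    covariate term (F-test; equals the Wald t-test for 1-df terms).
    P-values are Bonferroni-corrected across all feature x covariate
    tests. Constant features are skipped with a notice."""
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise InputError(f"covariate columns absent from cohort table: {missing}")

    rows = []
    for feature in feature_cols:
        sub = cohort[[feature, *covariates]].dropna()
        if len(sub) < 10:
            raise InputError(f"feature {feature}: fewer than 10 complete rows")
        if sub[feature].nunique() <= 1:
            logger.info("feature %s is constant; screen skipped", feature)
            continue
        model = smf.ols(_screen_formula(feature, covariates, sub), data=sub)
        if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
            raise InputError(
                f"feature {feature}: rank-deficient design; collinear columns among "
                f"{list(covariates)}")
        res = model.fit()
        anova = sm.stats.anova_lm(res, typ=2)
        for cov in covariates:
            term = [ix for ix in anova.index if f"'{cov}'" in ix]
            stat = float(anova.loc[term[0], "F"])
            p = float(anova.loc[term[0], "PR(>F)"])
            rows.append({"feature": feature, "covariate": cov,
                         "statistic": stat, "p_raw": p})
    if not rows:
        raise InputError("no testable features")
    table = pd.DataFrame(rows)
    n_tests = len(table)
    table["p_bonf"] = np.minimum(1.0, table["p_raw"] * n_tests)
    table["significant"] = table["p_bonf"] < alpha
    return ScreenResult(table=table, n_tests=n_tests, alpha=alpha)


# ---------------------------------------------------------------------------
# Ordinal regression


def encode_labels(labels) -> tuple[np.ndarray, tuple]:
    """Map visual labels to ordinal codes 0 < 1 < ... Strings use the
    fixed taxonomy poor < moderate < good; numeric labels keep their
    natural order; ordered categoricals keep their own order."""
    if isinstance(labels, pd.Series) and isinstance(labels.dtype, pd.CategoricalDtype):
        cats = list(labels.cat.categories)
        return labels.cat.codes.to_numpy(), tuple(cats)
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        order = [lab for lab in VISUAL_LABELS if lab in set(arr)]
        unknown = set(arr) - set(VISUAL_LABELS)
        if unknown:
            raise InputError(f"unknown visual labels {sorted(unknown)}; expected {VISUAL_LABELS}")
        lut = {lab: i for i, lab in enumerate(order)}
        return np.array([lut[v] for v in arr]), tuple(order)
    levels = np.unique(arr)
    lut = {v: i for i, v in enumerate(levels)}
    return np.array([lut[v] for v in arr]), tuple(levels)


@dataclasses.dataclass
class OrdinalQCResults:
    """Proportional-odds fit, reported on the raw feature scale."""

    feature_names: list[str]
    params: pd.Series            # raw-scale coefficients
    bse: pd.Series               # raw-scale standard errors
    odds_ratios: pd.Series
    conf_int: pd.DataFrame       # columns CI_low, CI_high (odds-ratio scale)
    pvalues: pd.Series
    cutpoints: np.ndarray        # raw-scale thresholds theta_k
    llf: float
    aic: float
    n_obs: int
    n_cutpoints: int
    params_standardized: pd.Series
    label_levels: tuple
    sm_params: np.ndarray | None = None   # optimizer-scale params, for warm starts

    def summary(self) -> pd.DataFrame:
        """Table shaped Parameter / OddsRatio / CI_low / CI_high / p."""
        return pd.DataFrame({
            "Parameter": self.feature_names,
            "OddsRatio": self.odds_ratios.values,
            "CI_low": self.conf_int["CI_low"].values,
            "CI_high": self.conf_int["CI_high"].values,
            "p": self.pvalues.values,
        })

    def save(self, path, domains: dict[str, str] | None = None) -> None:
        table = self.summary()
        if domains:
            table.insert(1, "Domain", [domains.get(f, "") for f in self.feature_names])
        table.to_csv(path, sep="\t", index=False)


class OrdinalQCModel:
    """Proportional-odds model of an ordinal visual label on QC features.

    Parameters
    ----------
    labels : array-like
        Ordinal outcome (strings from the poor/moderate/good taxonomy,
        numeric levels, or an ordered categorical).
    features : DataFrame
        Predictor columns; rows with any missing value are dropped
        (complete-case, counts logged).
    adjust : DataFrame, optional
        Extra covariate columns (e.g. site dummies, age, sex) included
        in the linear predictor but never candidates for elimination.
    """

    def __init__(self, labels, features: pd.DataFrame, adjust: pd.DataFrame | None = None):
        features = pd.DataFrame(features).astype(float)
        self.feature_names = list(features.columns)
        self.adjust_names = list(adjust.columns) if adjust is not None else []
        X = features if adjust is None else pd.concat([features, adjust.astype(float)], axis=1)
        y, self.label_levels = encode_labels(labels)
        keep = ~(X.isna().any(axis=1).to_numpy() | (y < 0))
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d incomplete rows (complete-case)", n_dropped)
        self.X = X.loc[keep]
        self.y = y[keep]
        if len(np.unique(self.y)) < 2:
            raise InputError("need at least 2 label levels present")
        self.n_obs = len(self.y)
        self._means = self.X.mean()
        sds = self.X.std(ddof=1)
        if (sds == 0).any():
            raise InputError(f"constant predictor(s): {list(sds.index[sds == 0])}")
        self._sds = sds
        self._Xs = (self.X - self._means) / self._sds
        self._sm_model = _FastOrderedLogit(self.y, self._Xs.to_numpy())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_cols: list[str],
                       label_col: str = "visual_label",
                       adjust_cols: list[str] | None = None) -> "OrdinalQCModel":
        adjust = df[adjust_cols] if adjust_cols else None
        return cls(df[label_col], df[feature_cols], adjust=adjust)

    @property
    def n_cutpoints(self) -> int:
        return len(np.unique(self.y)) - 1

    def null_llf(self) -> float:
        """Log-likelihood of the thresholds-only model (closed form from
        the label frequencies)."""
        _, counts = np.unique(self.y, return_counts=True)
        return float((counts * np.log(counts / counts.sum())).sum())

    def _check_converged(self, res, method: str, maxiter: int) -> None:
        """Accept an optimizer stop as converged when the per-observation
        mean score is tiny (bfgs can report precision loss after it has
        already driven the gradient below gtol)."""
        if res.mle_retvals.get("converged", True):
            return
        grad = np.max(np.abs(self._sm_model.score(np.asarray(res.params)))) / self.n_obs
        if grad < 1e-6:
            return
        raise FitError(
            f"ordinal fit did not converge after {maxiter} {method} iterations "
            f"(mean score {grad:.3g}): {res.mle_retvals}")

    def _fit_light(self, method: str = "bfgs", maxiter: int = 500,
                   start_params: np.ndarray | None = None) -> tuple[float, float, np.ndarray]:
        """Maximize the likelihood without computing standard errors
        (used for AIC comparisons during elimination).
        Returns (llf, aic, optimizer-scale params)."""
        with np.errstate(over="ignore"):
            res = self._sm_model.fit(method=method, maxiter=maxiter, disp=False,
                                     start_params=start_params, skip_hessian=True)
        self._check_converged(res, method, maxiter)
        llf = float(res.llf)
        aic = -2.0 * llf + 2.0 * (self.X.shape[1] + self.n_cutpoints)
        return llf, aic, np.asarray(res.params)

    def fit(self, method: str = "bfgs", maxiter: int = 500,
            start_params: np.ndarray | None = None) -> OrdinalQCResults:
        extra = {"gtol": 1e-8} if method == "bfgs" else {}
        with np.errstate(over="ignore"):
            res = self._sm_model.fit(method=method, maxiter=maxiter, disp=False,
                                     start_params=start_params, **extra)
        self._check_converged(res, method, maxiter)
        k = self.X.shape[1]
        beta_std = np.asarray(res.params[:k])
        if np.any(np.abs(beta_std) > 30):
            raise FitError(
                "extreme standardized coefficients suggest complete separation; "
                "consider a penalized fit or pooling label levels")
        se_std = np.asarray(res.bse[:k])

        cols = list(self.X.columns)
        sds = self._sds.to_numpy()
        beta_raw = beta_std / sds
        se_raw = se_std / sds
        zcrit = stats.norm.ppf(0.975)
        ci_lo = np.exp(beta_raw - zcrit * se_raw)
        ci_hi = np.exp(beta_raw + zcrit * se_raw)
        with np.errstate(divide="ignore", invalid="ignore"):
            zvals = np.where(se_std > 0, beta_std / se_std, np.inf)
        pvals = 2 * stats.norm.sf(np.abs(zvals))

        # P(Y<=k) = F(theta_std - sum((x-m)/s * b_std))
        #         = F((theta_std + sum(m * b_raw)) - x'b_raw)
        theta_std = self._sm_model.transform_threshold_params(res.params)[1:-1]
        theta_raw = np.asarray(theta_std) + float(np.dot(self._means.to_numpy(), beta_raw))

        llf = float(res.llf)
        n_params = k + self.n_cutpoints
        feat_idx = [cols.index(f) for f in self.feature_names]
        return OrdinalQCResults(
            feature_names=list(self.feature_names),
            params=pd.Series(beta_raw[feat_idx], index=self.feature_names),
            bse=pd.Series(se_raw[feat_idx], index=self.feature_names),
            odds_ratios=pd.Series(np.exp(beta_raw[feat_idx]), index=self.feature_names),
            conf_int=pd.DataFrame({"CI_low": ci_lo[feat_idx], "CI_high": ci_hi[feat_idx]},
                                  index=self.feature_names),
            pvalues=pd.Series(pvals[feat_idx], index=self.feature_names),
            cutpoints=theta_raw,
            llf=llf,
            aic=-2.0 * llf + 2.0 * n_params,
            n_obs=self.n_obs,
            n_cutpoints=self.n_cutpoints,
            params_standardized=pd.Series(beta_std, index=cols),
            label_levels=self.label_levels,
            sm_params=np.asarray(res.params),
        )

    def refit_without(self, feature: str) -> "OrdinalQCModel":
        """A new model with one feature column removed (adjustment
        columns are retained)."""
        if feature not in self.feature_names:
            raise InputError(f"{feature!r} is not a removable feature")
        remaining = [f for f in self.feature_names if f != feature]
        adjust = self.X[self.adjust_names] if self.adjust_names else None
        model = OrdinalQCModel.__new__(OrdinalQCModel)
        model.feature_names = remaining
        model.adjust_names = list(self.adjust_names)
        model.X = self.X[remaining + self.adjust_names]
        model.y = self.y
        model.label_levels = self.label_levels
        model.n_obs = self.n_obs
        model._means = model.X.mean()
        model._sds = model.X.std(ddof=1)
        model._Xs = (model.X - model._means) / model._sds
        model._sm_model = _FastOrderedLogit(model.y, model._Xs.to_numpy())
        return model


# ---------------------------------------------------------------------------
# Backward elimination and model comparison


@dataclasses.dataclass
class RemovalStep:
    removed: str
    aic_before: float
    aic_after: float


def backward_eliminate_aic(model: OrdinalQCModel, method: str = "bfgs",
                           ) -> tuple[OrdinalQCResults, list[RemovalStep]]:
    """Greedy backward elimination on AIC.

    At each step every single-feature removal is refitted; the removal
    with the lowest AIC is accepted if it lowers AIC, otherwise the
    procedure stops. The thresholds-only model (closed-form likelihood)
    is the candidate when one removable feature remains, so the loop is
    total. The returned AIC never exceeds the full model's.
    """
    current_model = model
    full_res = model.fit(method=method)
    current_aic, current_params = full_res.aic, full_res.sm_params
    log: list[RemovalStep] = []
    null_model = False
    while current_model.feature_names:
        candidates: list[tuple[float, str, OrdinalQCModel | None, np.ndarray | None]] = []
        for feature in current_model.feature_names:
            if len(current_model.feature_names) == 1 and not current_model.adjust_names:
                null_aic = -2.0 * current_model.null_llf() + 2.0 * current_model.n_cutpoints
                candidates.append((null_aic, feature, None, None))
                continue
            sub = current_model.refit_without(feature)
            # Warm start: current optimum with the dropped coefficient excised.
            j = current_model.feature_names.index(feature)
            start = np.delete(current_params, j) if current_params is not None else None
            try:
                _, sub_aic, sub_params = sub._fit_light(method=method, start_params=start)
            except FitError:
                continue
            candidates.append((sub_aic, feature, sub, sub_params))
        if not candidates:
            break
        best_aic, best_feature, best_model, best_params = min(candidates,
                                                              key=lambda c: (c[0], c[1]))
        if best_aic >= current_aic:
            break
        log.append(RemovalStep(removed=best_feature, aic_before=current_aic,
                               aic_after=best_aic))
        if best_model is None:   # thresholds-only model won
            null_model = True
            break
        current_model, current_aic, current_params = best_model, best_aic, best_params

    if null_model:
        null_llf = current_model.null_llf()
        reduced = dataclasses.replace(
            full_res, feature_names=[], params=pd.Series(dtype=float),
            bse=pd.Series(dtype=float), odds_ratios=pd.Series(dtype=float),
            conf_int=pd.DataFrame(columns=["CI_low", "CI_high"]),
            pvalues=pd.Series(dtype=float), llf=null_llf,
            aic=-2.0 * null_llf + 2.0 * current_model.n_cutpoints,
            params_standardized=pd.Series(dtype=float), sm_params=None)
    elif current_model is model:
        reduced = full_res
    else:
        reduced = current_model.fit(method=method, start_params=current_params)
    return reduced, log


@dataclasses.dataclass
class LRComparison:
    lr: float
    df: int
    pvalue: float


def compare_models(full: OrdinalQCResults, reduced: OrdinalQCResults) -> LRComparison:
    """Likelihood-ratio test of a reduced model nested in a full one:
    LR = 2 (llf_full - llf_reduced), df = parameter-count difference."""
    if not set(reduced.feature_names) <= set(full.feature_names):
        raise InputError("models are not nested: reduced features must be a subset")
    if reduced.n_obs != full.n_obs:
        raise InputError("models were fitted on different observation sets")
    df = len(full.feature_names) - len(reduced.feature_names)
    lr = max(0.0, 2.0 * (full.llf - reduced.llf))
    pvalue = 1.0 if df == 0 else float(stats.chi2.sf(lr, df))
    return LRComparison(lr=lr, df=df, pvalue=pvalue)


def save_removal_log(log: list[RemovalStep], path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in log]).to_csv(path, sep="\t", index=False)
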