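"""Cohort statistics: screening, balanced logistic modelling, ROC, survival.

The analysis chain mirrors standard clinical-prediction practice for a
class-imbalanced binary outcome (~80/20 improved vs not improved):

1. univariate screening of candidate predictors (p < 0.2), with the test
   chosen by distribution: Shapiro-Wilk normal in both groups -> Welch t,
   otherwise Mann-Whitney; categorical -> chi-square, or Fisher's exact
   when an expected cell is below 5;
2. a stratified train/test partition;
3. ROSE-style smoothed-bootstrap oversampling of the training set to a
   ~50/50 class mix;
4. multivariable logistic regression with backward stepwise elimination,
   reported with odds ratios, Wald CIs, Hosmer-Lemeshow calibration and
   Nagelkerke R^2, optionally as a bagged ensemble of balanced refits;
5. ROC analysis with a DeLong confidence interval and a Youden-J cutoff;
6. Kaplan-Meier curves with log-rank comparison and a hazard ratio.

The modelling pieces are also exposed as sklearn-style estimators
(:class:`ROSESampler`, :class:`BaggedROSELogistic`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "ScreenResult",
    "ModelReport",
    "RocResult",
    "SurvivalComparison",
    "SeparationError",
    "compare_groups",
    "screen_variables",
    "stratified_partition",
    "rose_balance",
    "ROSESampler",
    "hosmer_lemeshow",
    "nagelkerke_r2",
    "fit_logistic_stepwise",
    "BaggedROSELogistic",
    "bagged_ensemble",
    "roc_analysis",
    "km_logrank",
]

SCREEN_P = 0.2          # univariate screening threshold
SHAPIRO_P = 0.05        # normality threshold for test selection
STAY_P = 0.05           # backward-elimination retention threshold
DEFAULT_SEED = 20231114
DEFAULT_ENSEMBLE_SIZE = 100
HORIZON_DAYS = 730      # 2-year landmark


class SeparationError(RuntimeError):
    """The logistic likelihood is degenerate (perfect separation)."""


# ---------------------------------------------------------------------------
# univariate screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    variable: str
    test: str            # welch_t | mann_whitney | chi2 | fisher
    p_value: float
    passes_screen: bool

    def __post_init__(self):
        if self.passes_screen != (self.p_value < SCREEN_P):
            raise ValueError("passes_screen must equal (p < 0.2)")


def _screen(variable: str, test: str, p: float) -> ScreenResult:
    p = float(p)
    return ScreenResult(variable, test, p, p < SCREEN_P)


def compare_groups(
    values_by_group: Mapping[object, Sequence],
    variable_kind: str,
    variable: str = "",
) -> ScreenResult:
    """Two-group comparison with distribution-driven test selection.

    Continuous variables: Shapiro-Wilk in each group; Welch t if both are
    compatible with normality (p >= 0.05), Mann-Whitney otherwise.
    Categorical variables: chi-square on the contingency table, Fisher's
    exact when any expected cell count falls below 5 (2x2 tables).
    """
    if len(values_by_group) != 2:
        raise ValueError(f"need exactly two groups, got {len(values_by_group)}")
    (ka, a), (kb, b) = values_by_group.items()
    a, b = np.asarray(a), np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"empty group among {ka!r}/{kb!r}")
    if variable_kind == "continuous":
        a, b = a.astype(float), b.astype(float)
        if a.size < 3 or b.size < 3:
            raise ValueError("continuous comparison needs n >= 3 per group")
        normal = (
            _shapiro_p(a) >= SHAPIRO_P and _shapiro_p(b) >= SHAPIRO_P
        )
        if normal:
            return _screen(variable, "welch_t",
                           sps.ttest_ind(a, b, equal_var=False).pvalue)
        return _screen(variable, "mann_whitney",
                       sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if variable_kind == "categorical":
        table = pd.crosstab(
            np.concatenate([np.zeros(a.size, int), np.ones(b.size, int)]),
            np.concatenate([a, b]),
        ).to_numpy()
        if table.shape[1] < 2:
            return _screen(variable, "chi2", 1.0)  # single level: no contrast
        chi2, p, dof, expected = sps.chi2_contingency(table)
        if expected.min() < 5 and table.shape == (2, 2):
            return _screen(variable, "fisher", sps.fisher_exact(table).pvalue)
        return _screen(variable, "chi2", p)
    raise ValueError(f"unknown variable_kind {variable_kind!r}")


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # degenerate constant sample: treat as non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def screen_variables(
    df: pd.DataFrame,
    outcome: str,
    variables: Sequence[str],
    kinds: Mapping[str, str] | None = None,
) -> list[ScreenResult]:
    """Screen each candidate against a binary outcome column."""
    y = df[outcome]
    levels = sorted(pd.unique(y.dropna()))
    if len(levels) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary, got {levels}")
    results = []
    for var in variables:
        kind = (kinds or {}).get(
            var, "continuous" if pd.api.types.is_numeric_dtype(df[var])
            and df[var].nunique() > 4 else "categorical"
        )
        sub = df[[var, outcome]].dropna()
        groups = {lv: sub.loc[sub[outcome] == lv, var].to_numpy()
                  for lv in levels}
        results.append(compare_groups(groups, kind, variable=var))
    return results


# ---------------------------------------------------------------------------
# partition and balancing
# ---------------------------------------------------------------------------

def stratified_partition(
    records: pd.DataFrame,
    outcome,
    train_fraction: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome-stratified train/test split, reproducible under ``seed``.

    Class proportions in the training set match the overall proportion to
    within one patient; the two parts are disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = records[outcome] if isinstance(outcome, str) else pd.Series(
        np.asarray(outcome), index=records.index)
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for level in sorted(pd.unique(y), key=str):
        members = records.index[(y == level).to_numpy()].to_numpy()
        if members.size < 2:
            raise ValueError(
                f"class {level!r} has {members.size} member(s); need >= 2"
            )
        members = members[rng.permutation(members.size)]
        n_train = int(round(train_fraction * members.size))
        if n_train == 0 or n_train == members.size:
            raise ValueError(
                f"train_fraction {train_fraction} leaves class {level!r} "
                "absent from one partition"
            )
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    return records.loc[sorted(train_idx, key=_key)], records.loc[
        sorted(test_idx, key=_key)]


def _key(x):
    return (str(type(x)), x)


def rose_bandwidth(n_k: int, q: int, sd: np.ndarray, shrink: float = 1.0):
    """Per-dimension smoothed-bootstrap bandwidth h_j.

    h_j = (4 / ((q + 2) n_k))^(1/(q+4)) * sd_j, scaled by ``shrink``
    (shrink = 0 degrades to a plain bootstrap).
    """
    const = (4.0 / ((q + 2) * n_k)) ** (1.0 / (q + 4))
    return shrink * const * np.asarray(sd, dtype=float)


def rose_balance(
    X,
    y,
    n_out: Optional[int] = None,
    shrink: float = 1.0,
    seed=None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Random Over-Sampling Examples: a smoothed-bootstrap balanced sample.

    Each synthetic observation picks its class with probability 1/2, draws a
    seed point uniformly from that class, and perturbs every continuous
    predictor with zero-mean Gaussian noise of bandwidth
    ``(4/((q+2) n_k))^(1/(q+4)) * sd_j`` (q predictors, class size n_k,
    within-class SD sd_j).
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("rose_balance needs both classes present")
    if classes.size > 2:
        raise ValueError("rose_balance supports binary outcomes only")
    rng = np.random.default_rng(seed)
    n_out = int(n_out if n_out is not None else len(y))
    q = X.shape[1]
    Xv = X.to_numpy(dtype=float)
    picks = rng.integers(0, 2, size=n_out)
    out = np.empty((n_out, q))
    y_out = np.empty(n_out, dtype=y.dtype)
    for c_idx, cls in enumerate(classes):
        members = np.flatnonzero(y == cls)
        sd = Xv[members].std(axis=0, ddof=1) if members.size > 1 else np.zeros(q)
        h = rose_bandwidth(members.size, q, sd, shrink)
        rows = np.flatnonzero(picks == c_idx)
        seeds = members[rng.integers(0, members.size, size=rows.size)]
        noise = rng.standard_normal((rows.size, q)) * h
        out[rows] = Xv[seeds] + noise
        y_out[rows] = cls
    return pd.DataFrame(out, columns=X.columns), y_out


class ROSESampler(BaseEstimator):
    """sklearn-style resampler wrapping :func:`rose_balance`."""

    def __init__(self, n_out=None, shrink=1.0, random_state=None):
        self.n_out = n_out
        self.shrink = shrink
        self.random_state = random_state

    def fit_resample(self, X, y):
        return rose_balance(
            X, y, n_out=self.n_out, shrink=self.shrink, seed=self.random_state
        )


# ---------------------------------------------------------------------------
# logistic modelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must lie in [0, 1]")
        lo, hi = self.auc_ci
        if not lo <= self.auc <= hi:
            raise ValueError("CI must bracket the AUC point estimate")


@dataclass(frozen=True)
class ModelReport:
    """Fitted predictor set with inference, calibration and discrimination."""

    retained: list[str]
    coefficients: dict[str, float]
    odds_ratios: dict[str, tuple[float, float, float]]  # OR, lo95, hi95
    p_values: dict[str, float]
    hosmer_lemeshow: tuple[float, float]                # statistic, p
    nagelkerke_r2: float
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    cutoff_scale: str        # "predictor" (single retained) or "probability"
    ensemble_size: int
    n_obs: int

    def __post_init__(self):
        for name, (orr, lo, hi) in self.odds_ratios.items():
            if not lo <= orr <= hi:
                raise ValueError(f"CI must bracket OR for {name}")
        if not 0 <= self.nagelkerke_r2 <= 1 + 1e-12:
            raise ValueError("Nagelkerke R^2 must be in [0, 1]")
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "retained": list(self.retained),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "odds_ratios": {
                k: {"or": float(o), "ci_low": float(l), "ci_high": float(h)}
                for k, (o, l, h) in self.odds_ratios.items()
            },
            "p_values": {k: float(v) for k, v in self.p_values.items()},
            "hosmer_lemeshow": {
                "statistic": float(self.hosmer_lemeshow[0]),
                "p_value": float(self.hosmer_lemeshow[1]),
            },
            "nagelkerke_r2": float(self.nagelkerke_r2),
            "auc": float(self.auc),
            "auc_ci": [float(self.auc_ci[0]), float(self.auc_ci[1])],
            "cutoff": float(self.cutoff),
            "cutoff_scale": self.cutoff_scale,
            "ensemble_size": int(self.ensemble_size),
            "n_obs": int(self.n_obs),
        }


def hosmer_lemeshow(
    y: np.ndarray, p: np.ndarray, n_groups: int = 10
) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness of fit over risk deciles (df = groups - 2)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="stable")
    stat = 0.0
    for grp in np.array_split(order, n_groups):
        if grp.size == 0:
            continue
        o1 = y[grp].sum()
        e1 = p[grp].sum()
        pbar = e1 / grp.size
        denom = grp.size * pbar * (1.0 - pbar)
        if denom <= 0:
            continue
        stat += (o1 - e1) ** 2 / denom
    df = n_groups - 2
    return float(stat), float(sps.chi2.sf(stat, df))


def nagelkerke_r2(llf: float, llnull: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from model and null log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 / n * (llnull - llf))
    max_cs = 1.0 - np.exp(2.0 / n * llnull)
    if max_cs <= 0:
        return 0.0
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Fit a logistic model with intercept; raise SeparationError cleanly."""
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("ignore", category=FutureWarning)
            res = sm.Logit(np.asarray(y, dtype=float), design).fit(
                disp=0, maxiter=200
            )
    except Exception as exc:  # statsmodels PerfectSeparation*, LinAlgError
        raise SeparationError(
            f"logistic fit failed for predictors {list(X.columns)}: {exc}"
        ) from exc
    coefs = res.params.drop("const", errors="ignore")
    if np.any(np.abs(coefs.to_numpy()) > 1e3) or np.any(
        res.bse.to_numpy() > 1e4
    ):
        worst = coefs.abs().idxmax() if len(coefs) else "const"
        raise SeparationError(f"separation detected in predictor {worst!r}")
    return res


def fit_logistic_stepwise(
    train: pd.DataFrame,
    outcome,
    candidates: Sequence[str],
    alpha_stay: float = STAY_P,
    criterion: str = "pvalue",
    ensemble_size: int = 0,
) -> ModelReport:
    """Backward stepwise logistic regression over screened candidates.

    With ``criterion='pvalue'`` the largest-p predictor is dropped until all
    Wald p-values fall below ``alpha_stay``; ``criterion='aic'`` drops the
    predictor whose removal lowers the AIC most, until none does.  Reports
    odds ratios with Wald 95% CIs, Hosmer-Lemeshow calibration over risk
    deciles, Nagelkerke R^2, in-sample AUC with a DeLong CI, and the
    Youden-J cutoff (on the predictor scale when one predictor is retained,
    otherwise on the predicted-probability scale).
    """
    if len(candidates) == 0:
        raise ValueError("need at least one candidate predictor")
    y = (train[outcome] if isinstance(outcome, str)
         else pd.Series(np.asarray(outcome), index=train.index))
    y = _binary01(y)
    n = len(y)
    events = int(min(y.sum(), n - y.sum()))
    epv = events / len(candidates)
    if epv < 10:
        warnings.warn(
            f"events-per-variable is {epv:.1f} (<10); estimates may be "
            "unstable", stacklevel=2,
        )
    cols = list(candidates)
    res = _fit_logit(y, train[cols])
    if criterion == "pvalue":
        while cols:
            pvals = res.pvalues.drop("const", errors="ignore")
            if pvals.max() < alpha_stay:
                break
            cols.remove(pvals.idxmax())
            res = _fit_logit(y, train[cols])
    elif criterion == "aic":
        while cols:
            trial = {
                c: _fit_logit(y, train[[k for k in cols if k != c]]).aic
                for c in cols
            }
            best = min(trial, key=trial.get)
            if trial[best] >= res.aic:
                break
            cols.remove(best)
            res = _fit_logit(y, train[cols])
    else:
        raise ValueError("criterion must be 'pvalue' or 'aic'")

    probs = np.asarray(res.predict())
    hl = hosmer_lemeshow(y.to_numpy(), probs)
    r2 = nagelkerke_r2(res.llf, res.llnull, n)
    ci = res.conf_int()
    odds = {
        name: (float(np.exp(res.params[name])),
               float(np.exp(ci.loc[name, 0])),
               float(np.exp(ci.loc[name, 1])))
        for name in cols
    }
    if cols:
        roc = roc_analysis(probs, y.to_numpy())
        if len(cols) == 1:
            name = cols[0]
            b0 = float(res.params["const"])
            b1 = float(res.params[name])
            p_cut = min(max(roc.cutoff, 1e-12), 1 - 1e-12)
            cutoff = (np.log(p_cut / (1 - p_cut)) - b0) / b1
            cutoff_scale = "predictor"
        else:
            cutoff, cutoff_scale = roc.cutoff, "probability"
        auc, auc_ci = roc.auc, roc.auc_ci
    else:
        auc, auc_ci, cutoff, cutoff_scale = 0.5, (0.5, 0.5), 0.5, "probability"
    return ModelReport(
        retained=cols,
        coefficients={k: float(v) for k, v in res.params.items()},
        odds_ratios=odds,
        p_values={k: float(v) for k, v in res.pvalues.items()},
        hosmer_lemeshow=hl,
        nagelkerke_r2=r2,
        auc=auc,
        auc_ci=auc_ci,
        cutoff=float(cutoff),
        cutoff_scale=cutoff_scale,
        ensemble_size=int(ensemble_size),
        n_obs=n,
    )


def _binary01(y) -> pd.Series:
    y = pd.Series(y).reset_index(drop=True)
    levels = sorted(pd.unique(y), key=str)
    if len(levels) != 2:
        raise ValueError(f"outcome must be binary, got levels {levels}")
    return (y == levels[1]).astype(float)


# ---------------------------------------------------------------------------
# bagged balanced ensemble
# ---------------------------------------------------------------------------

class BaggedROSELogistic(BaseEstimator, ClassifierMixin):
    """Bagged logistic regression on ROSE-balanced bootstrap resamples.

    Each of ``n_models`` members refits a plain logistic model on a
    bootstrap resample of the training data, balanced to ~50/50 by the
    smoothed bootstrap; the ensemble prediction is the mean predicted
    probability (``aggregate='vote'`` uses the member majority instead).
    Members that fail to fit (e.g. separation in a resample) are skipped
    with a warning.
    """

    def __init__(self, n_models=DEFAULT_ENSEMBLE_SIZE, shrink=1.0,
                 balance=True, bootstrap=True, aggregate="mean",
                 random_state=None):
        self.n_models = n_models
        self.shrink = shrink
        self.balance = balance
        self.bootstrap = bootstrap
        self.aggregate = aggregate
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        X = pd.DataFrame(X).reset_index(drop=True)
        y01 = _binary01(y).to_numpy()
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        n = len(y01)
        members = []
        failures = 0
        for _ in range(self.n_models):
            if self.bootstrap:
                idx = rng.integers(0, n, size=n)
                Xb, yb = X.iloc[idx], y01[idx]
            else:
                Xb, yb = X, y01
            if np.unique(yb).size < 2:
                failures += 1
                continue
            if self.balance:
                Xb, yb = rose_balance(
                    Xb, yb, shrink=self.shrink,
                    seed=rng.integers(0, 2**31 - 1),
                )
            try:
                res = _fit_logit(pd.Series(yb), Xb)
            except SeparationError:
                failures += 1
                continue
            members.append(res.params.reindex(
                ["const", *X.columns]).to_numpy())
        if failures:
            warnings.warn(
                f"{failures}/{self.n_models} ensemble members failed and "
                "were skipped", stacklevel=2,
            )
        if not members:
            raise RuntimeError("all ensemble members failed to fit")
        self.members_ = np.vstack(members)
        return self

    def _member_probs(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        design = np.column_stack(
            [np.ones(len(X)), X[list(self.feature_names_in_)].to_numpy(float)]
        )
        eta = design @ self.members_.T
        return 1.0 / (1.0 + np.exp(-eta))  # (n_obs, n_members)

    def predict_proba(self, X) -> np.ndarray:
        probs = self._member_probs(X)
        if self.aggregate == "mean":
            p1 = probs.mean(axis=1)
        elif self.aggregate == "vote":
            p1 = (probs >= 0.5).mean(axis=1)
        else:
            raise ValueError("aggregate must be 'mean' or 'vote'")
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def bagged_ensemble(
    train: pd.DataFrame,
    outcome,
    predictors: Sequence[str],
    n_models: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = DEFAULT_SEED,
    **kwargs,
) -> BaggedROSELogistic:
    """Fit a :class:`BaggedROSELogistic` on cohort-table columns."""
    y = train[outcome] if isinstance(outcome, str) else outcome
    est = BaggedROSELogistic(n_models=n_models, random_state=seed, **kwargs)
    return est.fit(train[list(predictors)], y)


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via structural components."""
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    tz = sps.rankdata(all_scores)
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v01 = (tz[:m] - tx) / n          # per-positive placement values
    v10 = 1.0 - (tz[m:] - ty) / m    # per-negative placement values
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return s01 / m + s10 / n


def roc_analysis(scores, labels, alpha: float = 0.05) -> RocResult:
    """Empirical ROC with trapezoidal AUC, DeLong CI and Youden-J cutoff.

    The trapezoidal AUC equals the Mann-Whitney concordance probability.
    The cutoff maximizes Youden's J = sensitivity + specificity - 1, with
    ties resolved toward the lower cutoff; a score >= cutoff predicts the
    positive class.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary01(labels).to_numpy().astype(int)
    if y.min() == y.max():
        raise ValueError("ROC analysis needs both classes present")
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    pos, neg = scores[y == 1], scores[y == 0]
    var = _delong_variance(pos, neg)
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    finite = thresholds[best][np.isfinite(thresholds[best])]
    cutoff = float(finite.min()) if finite.size else float(scores.max())
    return RocResult(auc=auc, auc_ci=ci, cutoff=cutoff,
                     fpr=fpr, tpr=tpr, thresholds=thresholds)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalComparison:
    """Kaplan-Meier comparison of two groups at a fixed horizon."""

    groups: tuple
    curves: dict            # group -> (times, survival probabilities)
    logrank_statistic: float
    logrank_p: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    mortality_at_horizon: dict  # group -> 1 - S(horizon)
    horizon_days: float

    def __post_init__(self):
        for g, (t, s) in self.curves.items():
            s = np.asarray(s)
            if s.size and (s[0] > 1 + 1e-12 or np.any(np.diff(s) > 1e-12)):
                raise ValueError(f"survival curve for {g!r} must be "
                                 "non-increasing from 1")


def km_logrank(
    times,
    events,
    groups,
    horizon: float = HORIZON_DAYS,
) -> SurvivalComparison:
    """Product-limit curves, log-rank test and hazard ratio for two groups.

    ``events`` is 1/True for an observed death, 0/False for censoring.  The
    hazard ratio comes from a single-covariate Cox proportional-hazards fit
    (second group vs first, groups ordered by label); cumulative mortality
    at ``horizon`` days is read from each curve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups), key=str)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if events.sum() == 0:
        raise ValueError("no events observed; survival comparison undefined")
    curves = {}
    mortality = {}
    for lab in labels:
        sel = groups == lab
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        surv = kmf.survival_function_
        curves[lab] = (
            surv.index.to_numpy(dtype=float),
            surv.iloc[:, 0].to_numpy(dtype=float),
        )
        mortality[lab] = float(1.0 - kmf.predict(horizon))
    a, b = (groups == labels[0]), (groups == labels[1])
    lr = logrank_test(times[a], times[b], events[a], events[b])
    df = pd.DataFrame({
        "time": times,
        "event": events.astype(int),
        "group": (groups == labels[1]).astype(int),
    })
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["group"]))
    ci_tbl = cph.confidence_intervals_
    with np.errstate(over="ignore"):
        hr_ci = (
            float(np.exp(ci_tbl.iloc[0, 0])),
            float(np.exp(ci_tbl.iloc[0, 1])),
        )
    return SurvivalComparison(
        groups=tuple(labels),
        curves=curves,
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hazard_ratio=hr,
        hr_ci=hr_ci,
        mortality_at_horizon=mortality,
        horizon_days=float(horizon),
    )
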