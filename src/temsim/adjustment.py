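"""Confounding-adjustment methods for subgroup and interaction effects.

Four methods are implemented, each returning the subgroup-specific treatment
effects b_{T|M=1}, b_{T|M=0} and the treatment-effect-modification (TEM)
estimate b_TM = b_{T|M=1} - b_{T|M=0} with model standard errors:

1. regression     -- outcome regression adjusting directly for confounders
2. ps_covariate   -- estimated propensity score entered as a linear covariate
3. iptw           -- inverse-probability-of-treatment weighted regression
4. ps_matching    -- 1:1 nearest-neighbour propensity matching with replacement

Each is crossed with four *adjustment models* describing how the moderator
enters the confounder adjustment (the propensity model for the PS methods,
the outcome model for regression adjustment):

a. main effects of M and the confounders only
b. (a) plus the single M x X1 product term
c. (a) plus all moderator-confounder product terms
d. fully stratified: separate fits within each level of M

The outcome model for the PS-based methods is Y ~ T + M + T*M (plus the PS
for covariate adjustment), i.e. the PS alone carries the confounder
adjustment; adding the raw confounders as well would make the estimators
doubly robust, which is outside this toolkit's scope.  IPTW and matching
use HC1 sandwich standard errors; matching realises frequency weights by
row replication so reused controls enter the sandwich as replications.

The primary interface is :class:`TEMEstimator`, a scikit-learn style
estimator; :func:`estimate_effects` is a thin functional wrapper around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .dgp import Cohort

__all__ = [
    "Method", "AdjustmentModel", "AdjustmentSpec", "PropensityFit", "MatchResult",
    "EffectEstimates", "EstimationError", "covariate_set", "fit_propensity",
    "iptw_weights", "nn_match", "estimate_effects", "estimate_all", "TEMEstimator",
]


class Method(str, Enum):
    REGRESSION = "regression"
    PS_COVARIATE = "ps_covariate"
    IPTW = "iptw"
    PS_MATCHING = "ps_matching"


class AdjustmentModel(str, Enum):
    MAIN_EFFECTS = "a"
    ONE_INTERACTION = "b"
    ALL_INTERACTIONS = "c"
    STRATIFIED = "d"


@dataclass(frozen=True)
class AdjustmentSpec:
    """One of the 16 method x adjustment-model combinations."""
    method: Method
    model: AdjustmentModel

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))
        object.__setattr__(self, "model", AdjustmentModel(self.model))


class EstimationError(RuntimeError):
    """A single replicate could not be estimated (empty stratum, separation,
    non-convergence); callers treat this as a replicate-level failure."""


@dataclass
class PropensityFit:
    """Fitted propensity scores P(T=1 | confounders, M)."""
    ps: np.ndarray
    coefficients: np.ndarray
    converged: bool
    stratified: bool = False

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.ps)) or np.any((self.ps <= 0.0) | (self.ps >= 1.0)):
            self.converged = False


@dataclass
class MatchResult:
    """Nearest-neighbour matches of controls to treated, with replacement.

    ``treated_idx[i]`` is matched to control ``control_idx[i]``; controls may
    repeat (their frequency weight is the repeat count).
    """
    treated_idx: np.ndarray
    control_idx: np.ndarray
    estimand_group: str = "treated"

    def control_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique matched control rows and their frequency weights."""
        return np.unique(self.control_idx, return_counts=True)

    def sample_indices(self) -> np.ndarray:
        """Row indices of the matched sample, controls repeated per use."""
        return np.concatenate([self.treated_idx, self.control_idx])


@dataclass
class EffectEstimates:
    """Subgroup treatment effects and the TEM estimate with model SEs."""
    bt_m1: float
    bt_m0: float
    btm: float
    se_m1: float
    se_m0: float
    se_tm: float
    converged: bool = True

    def __post_init__(self) -> None:
        assert abs(self.btm - (self.bt_m1 - self.bt_m0)) < 1e-10


_CONF = ["X1", "X2", "X3", "X4", "X5", "X6"]


def covariate_set(model: AdjustmentModel, confounders: list[str] | None = None) -> list[str]:
    """Design terms of an adjustment model (interactions written ``M:Xj``).

    For the stratified model the returned set is the per-stratum one (M is
    constant within a stratum and so drops out).
    """
    model = AdjustmentModel(model)
    conf = _CONF if confounders is None else list(confounders)
    if model is AdjustmentModel.MAIN_EFFECTS:
        return ["M"] + conf
    if model is AdjustmentModel.ONE_INTERACTION:
        return ["M"] + conf + [f"M:{conf[0]}"]
    if model is AdjustmentModel.ALL_INTERACTIONS:
        return ["M"] + conf + [f"M:{c}" for c in conf]
    return conf  # STRATIFIED


# ---------------------------------------------------------------------------
# array-level machinery (shared by TEMEstimator, estimate_all and the
# Monte Carlo driver; the public frame-level functions wrap these)

def _fit_logit(endog, exog):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(endog, exog).fit(disp=0, maxiter=100)
    except Exception:
        return np.full(len(endog), np.nan), np.full(exog.shape[1], np.nan), False
    return res.predict(exog), res.params, bool(res.mle_retvals.get("converged", False))


def _ps_design(t, m, X, model: AdjustmentModel):
    if model is AdjustmentModel.MAIN_EFFECTS:
        return np.column_stack([np.ones(len(t)), m, X])
    if model is AdjustmentModel.ONE_INTERACTION:
        return np.column_stack([np.ones(len(t)), m, X, m * X[:, 0]])
    if model is AdjustmentModel.ALL_INTERACTIONS:
        return np.column_stack([np.ones(len(t)), m, X, m[:, None] * X])
    raise ValueError(model)


def _fit_propensity_arrays(t, m, X, model: AdjustmentModel) -> PropensityFit:
    t = np.asarray(t, float)
    if t.min() == t.max():
        raise EstimationError("cohort needs both treated and untreated subjects")
    if model is not AdjustmentModel.STRATIFIED:
        ps, params, conv = _fit_logit(t, _ps_design(t, m, X, model))
        return PropensityFit(ps=ps, coefficients=params, converged=conv)
    ps = np.empty(len(t))
    coefs, conv = [], True
    for level in (0, 1):
        k = m == level
        if k.sum() == 0 or t[k].min() == t[k].max():
            raise EstimationError(f"stratum M={level} lacks treated or untreated subjects")
        exog = np.column_stack([np.ones(int(k.sum())), X[k]])
        ps[k], params, ok = _fit_logit(t[k], exog)
        coefs.append(params)
        conv &= ok
    return PropensityFit(ps=ps, coefficients=np.concatenate(coefs), converged=conv,
                         stratified=True)


def _ols(y, exog, robust=False, weights=None):
    model = sm.OLS(y, exog) if weights is None else sm.WLS(y, exog, weights=weights)
    return model.fit(cov_type="HC1" if robust else "nonrobust")


def _joint_effects(res) -> EffectEstimates:
    """Read subgroup effects off a fit of Y ~ 1 + T + M + T*M (+ extras):
    b_{T|M=0} is the T coefficient, b_TM the T*M coefficient."""
    cov = np.asarray(res.cov_params())
    b = np.asarray(res.params)
    bt, btm = b[1], b[3]
    return EffectEstimates(
        bt_m1=bt + btm, bt_m0=bt, btm=btm,
        se_m1=float(np.sqrt(cov[1, 1] + cov[3, 3] + 2.0 * cov[1, 3])),
        se_m0=float(np.sqrt(cov[1, 1])),
        se_tm=float(np.sqrt(cov[3, 3])),
    )


def _combine_strata(b1, se1, b0, se0) -> EffectEstimates:
    # independent stratum fits: SE of the difference adds in quadrature
    return EffectEstimates(bt_m1=b1, bt_m0=b0, btm=b1 - b0,
                           se_m1=se1, se_m0=se0,
                           se_tm=float(np.hypot(se1, se0)))


def _check_strata(t, m) -> None:
    for level in (0, 1):
        sel = t[m == level]
        if sel.size == 0 or sel.min() == sel.max():
            raise EstimationError(f"stratum M={level} lacks treated or untreated subjects")


def _joint_design(t, m, X, model: AdjustmentModel, ps=None):
    cols = [np.ones(len(t)), t, m, t * m]
    if ps is not None:                      # PS as a linear covariate
        cols.append(ps)
    elif model is AdjustmentModel.MAIN_EFFECTS:
        cols.append(X)
    elif model is AdjustmentModel.ONE_INTERACTION:
        cols.extend([X, m * X[:, 0]])
    elif model is AdjustmentModel.ALL_INTERACTIONS:
        cols.extend([X, m[:, None] * X])
    return np.column_stack(cols)


def _stratum_fit(y, t, extra_cols, robust=False, weights=None):
    exog = np.column_stack([np.ones(len(t)), t] + extra_cols)
    res = _ols(y, exog, robust=robust, weights=weights)
    return float(res.params[1]), float(res.bse[1])


def _estimate_core(y, t, m, X, method: Method, model: AdjustmentModel,
                   ps_fit: PropensityFit | None) -> EffectEstimates:
    """Dispatch one method x model combination on raw arrays.

    ``ps_fit`` must be the fit of the matching adjustment model for the
    three PS-based methods (stratified for model d); it is ignored by
    regression adjustment.
    """
    stratified = model is AdjustmentModel.STRATIFIED

    if method is Method.REGRESSION:
        if not stratified:
            return _joint_effects(_ols(y, _joint_design(t, m, X, model)))
        _check_strata(t, m)
        parts = {}
        for level in (0, 1):
            k = m == level
            parts[level] = _stratum_fit(y[k], t[k], [X[k]])
        return _combine_strata(*parts[1], *parts[0])

    if ps_fit is None:
        raise ValueError("PS-based methods need a fitted propensity model")
    if not ps_fit.converged:
        raise EstimationError("propensity model did not converge")
    ps = ps_fit.ps

    if method is Method.PS_COVARIATE:
        if not stratified:
            return _joint_effects(_ols(y, _joint_design(t, m, X, model, ps=ps)))
        _check_strata(t, m)
        parts = {}
        for level in (0, 1):
            k = m == level
            parts[level] = _stratum_fit(y[k], t[k], [ps[k]])
        return _combine_strata(*parts[1], *parts[0])

    if method is Method.IPTW:
        w = iptw_weights(ps, t)
        if not stratified:
            exog = np.column_stack([np.ones(len(t)), t, m, t * m])
            return _joint_effects(_ols(y, exog, robust=True, weights=w))
        _check_strata(t, m)
        parts = {}
        for level in (0, 1):
            k = m == level
            parts[level] = _stratum_fit(y[k], t[k], [], robust=True, weights=w[k])
        return _combine_strata(*parts[1], *parts[0])

    # PS matching: the matched-sample regression carries each treated
    # subject with weight 1 and each reused control with its match
    # frequency; the HC1 sandwich on the weighted fit (weights entering
    # the meat squared, as in Stata's pweight-robust convention) gives the
    # characteristic overestimation of the empirical SE
    def _match_rows_weights(ps_s, t_s):
        match = nn_match(ps_s, t_s)
        ctrl, counts = match.control_weights()
        rows = np.concatenate([match.treated_idx, ctrl])
        wts = np.concatenate([np.ones(len(match.treated_idx)), counts.astype(float)])
        return rows, wts

    if not stratified:
        idx, w = _match_rows_weights(ps, t)
        ym, tm_, mm = y[idx], t[idx], m[idx]
        exog = np.column_stack([np.ones(len(idx)), tm_, mm, tm_ * mm])
        return _joint_effects(_ols(ym, exog, robust=True, weights=w))
    _check_strata(t, m)
    parts = {}
    for level in (0, 1):
        k = np.flatnonzero(m == level)
        sub_idx, w = _match_rows_weights(ps[k], t[k])
        idx = k[sub_idx]
        parts[level] = _stratum_fit(y[idx], t[idx], [], robust=True, weights=w)
    return _combine_strata(*parts[1], *parts[0])


def _cohort_arrays(data: Cohort | pd.DataFrame):
    df = data.to_frame() if isinstance(data, Cohort) else data
    return (df["Y"].to_numpy(float) if "Y" in df else None,
            df["T"].to_numpy(float), df["M"].to_numpy(float),
            df[_CONF].to_numpy(float))


# ---------------------------------------------------------------------------
# public operations

def fit_propensity(data: Cohort | pd.DataFrame, model: AdjustmentModel) -> PropensityFit:
    """Fit the propensity model by maximum-likelihood logistic regression.

    For the stratified model two independent logistic fits (one per level
    of M) are recombined into a single score vector.
    """
    _, t, m, X = _cohort_arrays(data)
    return _fit_propensity_arrays(t, m, X, AdjustmentModel(model))


def iptw_weights(fit: PropensityFit | np.ndarray, t) -> np.ndarray:
    """Unstabilised, untrimmed inverse-probability-of-treatment weights:
    1/ps for the treated, 1/(1-ps) for the untreated."""
    ps = fit.ps if isinstance(fit, PropensityFit) else np.asarray(fit, float)
    t = np.asarray(t)
    if np.any((ps <= 0.0) | (ps >= 1.0)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    return np.where(t == 1, 1.0 / ps, 1.0 / (1.0 - ps))


def nn_match(fit: PropensityFit | np.ndarray, t) -> MatchResult:
    """Match each treated subject to its nearest control on the propensity
    score, with replacement and no calliper; exact distance ties are broken
    to the lowest control row index."""
    ps = fit.ps if isinstance(fit, PropensityFit) else np.asarray(fit, float)
    t = np.asarray(t)
    treated = np.flatnonzero(t == 1)
    controls = np.flatnonzero(t == 0)
    if controls.size == 0:
        raise EstimationError("no controls available for matching")
    order = np.argsort(ps[controls], kind="stable")
    sorted_controls = controls[order]
    cs = ps[sorted_controls]
    pt = ps[treated]
    pos = np.searchsorted(cs, pt)  # first control with ps >= pt
    n_c = cs.size
    left = np.clip(pos - 1, 0, n_c - 1)
    right = np.clip(pos, 0, n_c - 1)
    d_left = np.where(pos > 0, np.abs(pt - cs[left]), np.inf)
    d_right = np.where(pos < n_c, np.abs(cs[right] - pt), np.inf)
    # among duplicated ps values the first occurrence has the lowest row
    # index (stable sort of ascending indices), so resolve each side to it
    cand_left = sorted_controls[np.searchsorted(cs, cs[left])]
    cand_right = sorted_controls[right]
    use_left = (d_left < d_right) | ((d_left == d_right) & (cand_left < cand_right))
    matched = np.where(use_left, cand_left, cand_right)
    return MatchResult(treated_idx=treated, control_idx=matched)


class TEMEstimator(BaseEstimator):
    """Estimate subgroup treatment effects and their difference (the TEM
    effect) from observational data, under a chosen confounding-adjustment
    method and adjustment model.

    Parameters
    ----------
    method : str or Method, default "regression"
        One of ``"regression"``, ``"ps_covariate"``, ``"iptw"``,
        ``"ps_matching"``.
    adjustment_model : str or AdjustmentModel, default "a"
        ``"a"`` main effects only, ``"b"`` plus the moderator-by-first-
        confounder product, ``"c"`` plus all moderator-confounder products,
        ``"d"`` stratified by the moderator.
    treatment, moderator : str
        Column names of the binary treatment and moderator in ``X``.
    confounders : list of str or None
        Confounder columns; ``None`` uses every other column of ``X``.

    Attributes
    ----------
    effect_m1_, effect_m0_, tem_ : float
        Subgroup treatment effects and their difference.
    se_effect_m1_, se_effect_m0_, se_tem_ : float
        Model standard errors (HC1 sandwich for IPTW and matching).
    propensity_ : PropensityFit or None
        Fitted propensity model (PS-based methods only).
    converged_ : bool

    Examples
    --------
    >>> from temsim.dgp import DGPCoefficients, generate_cohort
    >>> cohort = generate_cohort(DGPCoefficients(), seed=7)
    >>> df = cohort.to_frame()
    >>> est = TEMEstimator(method="iptw", adjustment_model="c")
    >>> est.fit(df[["T", "M", "X1", "X2", "X3", "X4", "X5", "X6"]], df["Y"])
    TEMEstimator(adjustment_model='c', method='iptw')
    >>> print(round(est.tem_, 1))
    0.3
    """

    def __init__(self, method="regression", adjustment_model="a",
                 treatment: str = "T", moderator: str = "M",
                 confounders: list[str] | None = None):
        self.method = method
        self.adjustment_model = adjustment_model
        self.treatment = treatment
        self.moderator = moderator
        self.confounders = confounders

    def _arrays(self, X, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame with named columns")
        conf = self.confounders
        if conf is None:
            conf = [c for c in X.columns if c not in (self.treatment, self.moderator)]
        if not conf:
            raise ValueError("at least one confounder column is required")
        missing = [c for c in (self.treatment, self.moderator, *conf) if c not in X.columns]
        if missing:
            raise ValueError(f"missing columns in X: {missing}")
        t = X[self.treatment].to_numpy(float)
        m = X[self.moderator].to_numpy(float)
        for name, v in (("treatment", t), ("moderator", m)):
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError(f"{name} column must be binary 0/1")
        Xc = X[list(conf)].to_numpy(float)
        yv = np.asarray(y, float)
        if len(yv) != len(t):
            raise ValueError("X and y length mismatch")
        if not (np.all(np.isfinite(Xc)) and np.all(np.isfinite(yv))):
            raise ValueError("non-finite values in input data")
        self.confounder_names_ = list(conf)
        return yv, t, m, Xc

    def fit(self, X, y):
        """Fit the chosen adjustment method on one cohort.

        ``X`` is a DataFrame containing the treatment, moderator and
        confounder columns; ``y`` is the continuous outcome.
        """
        yv, t, m, Xc = self._arrays(X, y)
        method = Method(self.method)
        model = AdjustmentModel(self.adjustment_model)
        self.propensity_ = None
        if method is not Method.REGRESSION:
            self.propensity_ = _fit_propensity_arrays(t, m, Xc, model)
        est = _estimate_core(yv, t, m, Xc, method, model, self.propensity_)
        self.effect_m1_ = est.bt_m1
        self.effect_m0_ = est.bt_m0
        self.tem_ = est.btm
        self.se_effect_m1_ = est.se_m1
        self.se_effect_m0_ = est.se_m0
        self.se_tem_ = est.se_tm
        self.converged_ = est.converged
        self.estimates_ = est
        self.n_features_in_ = X.shape[1]
        return self


def estimate_effects(cohort: Cohort | pd.DataFrame, spec: AdjustmentSpec) -> EffectEstimates:
    """Estimate subgroup effects and the TEM effect for one cohort under one
    method x adjustment-model combination.

    Raises :class:`EstimationError` on empty strata or non-convergence; the
    simulation layer records these as failed replicates.
    """
    df = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    spec = AdjustmentSpec(spec.method, spec.model)
    est = TEMEstimator(method=spec.method, adjustment_model=spec.model,
                       confounders=_CONF)
    est.fit(df[["T", "M", *_CONF]], df["Y"])
    return est.estimates_


def estimate_all(cohort: Cohort | pd.DataFrame,
                 specs: list[AdjustmentSpec] | None = None,
                 ) -> dict[AdjustmentSpec, EffectEstimates | None]:
    """Estimate every requested method x model combination on one cohort,
    fitting each propensity model once and sharing it across the PS-based
    methods.  Combinations that fail map to ``None``.
    """
    y, t, m, X = _cohort_arrays(cohort)
    if specs is None:
        specs = [AdjustmentSpec(me, mo) for me in Method for mo in AdjustmentModel]
    ps_fits: dict[AdjustmentModel, PropensityFit | None] = {}
    for model in {s.model for s in specs if s.method is not Method.REGRESSION}:
        try:
            ps_fits[model] = _fit_propensity_arrays(t, m, X, model)
        except EstimationError:
            ps_fits[model] = None
    out: dict[AdjustmentSpec, EffectEstimates | None] = {}
    for spec in specs:
        ps_fit = ps_fits.get(spec.model) if spec.method is not Method.REGRESSION else None
        if spec.method is not Method.REGRESSION and ps_fit is None:
            out[spec] = None
            continue
        try:
            out[spec] = _estimate_core(y, t, m, X, spec.method, spec.model, ps_fit)
        except EstimationError:
            out[spec] = None
    return out
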