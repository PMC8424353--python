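"""Trend regressions on spatio-temporal genetic statistics.

Responses that live on the real line (allelic richness A_R, mean
relatedness r_w) are fitted by Gaussian maximum likelihood; responses in
(0, 1) (H_O, H_E, pairwise G''_ST) by beta regression with a logit link
and a common precision parameter.  Candidate models combine sampling
period (continuous index or categorical) and sampling area (or area
pair) as fixed effects; models are ranked by small-sample-corrected AIC
(AICc) and summarized with Akaike weights.  A two-sided exact sign test
checks whether consecutive-period changes in differentiation drift in one
direction more often than chance.

Confidence intervals are Wald intervals at the 97.5% two-sided level
(the reporting convention of the monitoring analysis this package
implements).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

#: two-sided confidence level used throughout
CI_LEVEL = 0.975
_Z = float(st.norm.ppf(1.0 - (1.0 - CI_LEVEL) / 2.0))

#: clamp applied to (0,1) responses before the beta likelihood
BETA_EPS = 1e-4

FORMULAS = ("time", "area", "time+area", "time*area", "period_cat", "period_cat+area")


@dataclass
class TrendFit:
    """One fitted candidate model with its information-criterion bookkeeping."""

    formula: str
    family: str
    params: pd.Series
    conf_int: pd.DataFrame  # columns lower/upper at CI_LEVEL
    loglik: float
    n_params: int  # all estimated parameters (incl. sigma or precision)
    n_obs: int
    aicc: float
    delta_aicc: float = float("nan")
    weight: float = float("nan")
    extra: dict = field(default_factory=dict)

    @property
    def slope(self) -> float:
        return float(self.params.get("time", np.nan))

    def slope_ci(self) -> tuple[float, float]:
        if "time" not in self.conf_int.index:
            return (float("nan"), float("nan"))
        lo, hi = self.conf_int.loc["time"]
        return float(lo), float(hi)


def aicc(loglik: float, p: int, n: int) -> float:
    """AICc = -2 logL + 2p + 2p(p+1)/(n - p - 1); requires n > p + 1."""
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n={n}, p={p} (needs n > p+1)")
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """omega_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _design(td: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Build the fixed-effects design matrix for one formula label.

    ``td`` needs columns ``time`` (ordered numeric period index), ``area``
    (categorical label; an area pair works the same way) and ``response``.
    """
    cols = {"const": np.ones(len(td))}
    if formula in ("time", "time+area", "time*area"):
        cols["time"] = td["time"].to_numpy(dtype=float)
    if formula in ("area", "time+area", "time*area", "period_cat+area"):
        dummies = pd.get_dummies(td["area"].astype(str), prefix="area", drop_first=True)
        for c in dummies:
            cols[c] = dummies[c].to_numpy(dtype=float)
    if formula == "time*area":
        dummies = pd.get_dummies(td["area"].astype(str), prefix="area", drop_first=True)
        for c in dummies:
            cols[f"time:{c}"] = td["time"].to_numpy(dtype=float) * dummies[c].to_numpy(
                dtype=float
            )
    if formula in ("period_cat", "period_cat+area"):
        dummies = pd.get_dummies(
            pd.Categorical(td["time"]), prefix="period", drop_first=True
        )
        for c in dummies.columns.astype(str):
            cols[str(c)] = dummies[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=td.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"singular design for formula {formula!r}: "
            f"rank {rank} < {X.shape[1]} columns {list(X.columns)}"
        )
    return X


def fit_linear_trend(td: pd.DataFrame, formula: str = "time") -> TrendFit:
    """Gaussian ML fit of ``response`` on the requested fixed effects.

    The parameter count for AICc includes the residual variance.
    """
    X = _design(td, formula)
    y = td["response"].to_numpy(dtype=float)
    if len(y) < X.shape[1] + 2:
        raise ValueError(f"too few rows ({len(y)}) for formula {formula!r}")
    res = sm.OLS(y, X).fit()
    p = X.shape[1] + 1  # + sigma
    ci = pd.DataFrame(
        {
            "lower": res.params - _Z * res.bse,
            "upper": res.params + _Z * res.bse,
        },
        index=res.params.index,
    )
    return TrendFit(
        formula=formula,
        family="linear",
        params=res.params,
        conf_int=ci,
        loglik=float(res.llf),
        n_params=p,
        n_obs=len(y),
        aicc=aicc(float(res.llf), p, len(y)),
        extra={"sigma2_ml": float(res.ssr / len(y))},
    )


def clamp_unit_interval(y: np.ndarray, eps: float = BETA_EPS) -> np.ndarray:
    """Clamp (0,1)-responses into [eps, 1-eps]; every clamped value is logged."""
    y = np.asarray(y, dtype=float)
    out = np.clip(y, eps, 1.0 - eps)
    n_clamped = int(np.sum(out != y))
    if n_clamped:
        logger.info("clamped %d boundary response(s) to [%g, %g]", n_clamped, eps, 1 - eps)
    return out


def fit_beta_logit_trend(td: pd.DataFrame, formula: str = "time") -> TrendFit:
    """Beta-regression ML fit (logit mean link, common precision).

    Coefficients are on the logit scale; the precision parameter counts
    toward AICc.  Responses are clamped away from 0/1 first.
    """
    X = _design(td, formula)
    y = clamp_unit_interval(td["response"].to_numpy(dtype=float))
    if len(y) < X.shape[1] + 2:
        raise ValueError(f"too few rows ({len(y)}) for formula {formula!r}")
    model = BetaModel(y, X)

    def _ok(r):
        if r.mle_retvals.get("converged", True):
            return True
        # optimizers may flag an abnormal line search at the optimum;
        # accept stationary points
        g = r.mle_retvals.get("gopt")
        return g is not None and float(np.max(np.abs(g))) < 1e-3

    with warnings.catch_warnings():
        # non-convergence is detected and handled below
        warnings.simplefilter("ignore", ConvergenceWarning)
        res = model.fit(disp=0, maxiter=500)
        if not _ok(res):
            # retry from the first solution with a gradient-free pass, then polish
            res = model.fit(start_params=res.params, method="nm", disp=0, maxiter=2000)
            res = model.fit(start_params=res.params, disp=0, maxiter=500)
    if not _ok(res):
        raise RuntimeError(
            f"beta regression did not converge for {formula!r}: {res.mle_retvals}"
        )
    mean_names = list(X.columns)
    params = pd.Series(np.asarray(res.params)[: len(mean_names)], index=mean_names)
    bse = pd.Series(np.asarray(res.bse)[: len(mean_names)], index=mean_names)
    ci = pd.DataFrame(
        {"lower": params - _Z * bse, "upper": params + _Z * bse}, index=mean_names
    )
    p = len(res.params)  # mean coefs + precision
    return TrendFit(
        formula=formula,
        family="beta",
        params=params,
        conf_int=ci,
        loglik=float(res.llf),
        n_params=p,
        n_obs=len(y),
        aicc=aicc(float(res.llf), p, len(y)),
        extra={"precision_param": float(np.asarray(res.params)[-1])},
    )


def model_selection(
    td: pd.DataFrame,
    family: str = "linear",
    formulas: tuple[str, ...] = FORMULAS,
) -> tuple[pd.DataFrame, list[TrendFit]]:
    """Fit all candidate formulas, rank by AICc, attach Akaike weights."""
    fitter = fit_linear_trend if family == "linear" else fit_beta_logit_trend
    fits: list[TrendFit] = []
    for f in formulas:
        try:
            fits.append(fitter(td, f))
        except (ValueError, RuntimeError) as exc:
            logger.warning("formula %r skipped: %s", f, exc)
    if not fits:
        raise RuntimeError("no candidate model could be fitted")
    a = np.array([f.aicc for f in fits])
    w = akaike_weights(a)
    for f, d, wi in zip(fits, a - a.min(), w):
        f.delta_aicc = float(d)
        f.weight = float(wi)
    fits.sort(key=lambda f: f.aicc)
    table = pd.DataFrame(
        {
            "model": [f.formula for f in fits],
            "p": [f.n_params for f in fits],
            "logLik": [f.loglik for f in fits],
            "AICc": [f.aicc for f in fits],
            "dAICc": [f.delta_aicc for f in fits],
            "weight": [f.weight for f in fits],
        }
    )
    return table, fits


def sign_test_differentiation(changes) -> tuple[int, int, float]:
    """Exact two-sided sign test on a series of consecutive-period changes.

    Zero changes (ties) are dropped and logged.  Returns ``(k_increases,
    n_nonzero_steps, p)`` where p doubles the smaller Binomial(n, 1/2)
    tail, capped at 1.
    """
    c = np.asarray(list(changes), dtype=float)
    nz = c[c != 0.0]
    n_ties = len(c) - len(nz)
    if n_ties:
        logger.info("sign test: dropped %d tied (zero) change(s)", n_ties)
    n = len(nz)
    if n == 0:
        raise ValueError("sign test needs at least one nonzero change")
    k = int(np.sum(nz > 0))
    # exact binomial tails in integer arithmetic
    lower = sum(math.comb(n, i) for i in range(k + 1))
    upper = sum(math.comb(n, i) for i in range(k, n + 1))
    p = min(1.0, 2.0 * min(lower, upper) / 2**n)
    return k, n, float(p)


def consecutive_changes(
    table: pd.DataFrame,
    value_col: str,
    period_col: str = "period",
    by: list[str] | None = None,
    period_order: list[str] | None = None,
) -> np.ndarray:
    """Pool consecutive-period differences of ``value_col`` within each
    ``by``-defined series (e.g. each area pair), in period order."""
    if period_order is not None:
        table = table.copy()
        table[period_col] = pd.Categorical(
            table[period_col], categories=period_order, ordered=True
        )
    out = []
    grouped = table.groupby(by, observed=True) if by else [(None, table)]
    for _, sub in grouped:
        sub = sub.sort_values(period_col)
        out.extend(np.diff(sub[value_col].to_numpy(dtype=float)))
    return np.asarray(out)
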