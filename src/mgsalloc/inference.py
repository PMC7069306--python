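"""Mixed-model fitting, collinearity diagnostics, LRT, marginal lines.

Each response (male variable cost, male fixed cost, female variable cost,
sex allocation) is modelled as a linear mixed model with fixed effects
MGSm + MGSf + body weight (no interactions) and a random intercept per
substrate shell, capturing micro-environmental correlation among
shell-mates. Coefficient tables use the restricted-likelihood (REML)
criterion; likelihood-ratio comparisons of nested fixed-effect
specifications refit both models by plain maximum likelihood, as required
for the log-likelihoods to be comparable. The fitting criterion is
recorded on every fit so results are auditable.

Collinearity between MGSm and MGSf (which are positively correlated by
construction — a long penis tends to sit in a dense neighbourhood) is
diagnosed with variance inflation factors; VIF > 10 is the conventional
harm threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Fixed-effect predictors of every response model, in design order.
PREDICTORS = ["mgs_m", "mgs_f", "body_weight"]

#: Response columns of the analysis table that can be modelled.
RESPONSES = ["male_variable", "male_fixed", "female_variable", "sex_allocation"]

# relative residual SS below this marks an exactly-linear response, where
# the mixed-model likelihood is degenerate and the GLS limit is plain OLS
_EXACT_FIT_RTOL = 1e-10


@dataclass
class LMMFit:
    """A fitted random-intercept linear mixed model for one response.

    ``params``/``bse``/``pvalues`` are keyed by ``intercept`` and the
    predictor names. ``re_var`` is the shell-intercept variance,
    ``resid_var`` the residual variance, both on the response scale.
    ``method`` records the fitting criterion (``REML``, ``ML``, or
    ``exact`` for a degenerate noiseless fit solved in closed form).
    """

    response: str
    predictors: list[str]
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    re_var: float
    resid_var: float
    loglik: float
    method: str
    n_obs: int
    n_groups: int
    converged: bool = True

    @property
    def intercept(self) -> float:
        return self.params["intercept"]


@dataclass(frozen=True)
class MarginalLine:
    """A fitted response line in one predictor, others held fixed."""

    vary: str
    slope: float
    intercept: float
    held: dict[str, float] = field(default_factory=dict)

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def _design(table: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    X = table[list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str] = PREDICTORS,
    reml: bool = True,
) -> LMMFit:
    """Fit ``response ~ predictors`` with a random intercept per shell.

    Parameters
    ----------
    table : DataFrame
        Analysis table with ``shell_id``, the predictors and the response.
    response : str
        Column to model (one of ``RESPONSES`` or any numeric column).
    predictors : sequence of str
        Fixed-effect columns; default MGSm + MGSf + body weight.
    reml : bool
        Restricted likelihood (default, for coefficient tables) or plain
        maximum likelihood (for likelihood-ratio comparisons).

    Raises
    ------
    ValueError
        On an empty table, a single shell (random intercept
        unidentifiable), or perfectly collinear predictors.
    """
    if len(table) == 0:
        raise ValueError("cannot fit on an empty analysis table")
    if response not in table.columns:
        raise ValueError(f"unknown response column {response!r}")
    groups = table["shell_id"]
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError(
            "random shell intercept unidentifiable with a single shell"
        )
    X = _design(table, predictors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("predictors are perfectly collinear")
    y = table[response].to_numpy(dtype=float)

    names = ["intercept", *predictors]

    # exactly-linear response: the mixed-model likelihood diverges as both
    # variance components go to zero; return the exact least-squares limit
    beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted_rss = float(np.sum((y - X @ beta) ** 2))
    scale_ref = float(np.sum((y - y.mean()) ** 2)) or 1.0
    if fitted_rss <= _EXACT_FIT_RTOL * scale_ref:
        return LMMFit(
            response=response,
            predictors=list(predictors),
            params=dict(zip(names, map(float, beta))),
            bse={n: 0.0 for n in names},
            pvalues={n: float("nan") for n in names},
            re_var=0.0,
            resid_var=0.0,
            loglik=float("inf"),
            method="exact",
            n_obs=len(y),
            n_groups=int(n_groups),
        )

    model = sm.MixedLM(y, X, groups=groups.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml)
    params = dict(zip(names, map(float, res.fe_params)))
    bse = dict(zip(names, map(float, res.bse_fe)))
    pvals = dict(zip(names, map(float, np.asarray(res.pvalues)[: len(names)])))
    return LMMFit(
        response=response,
        predictors=list(predictors),
        params=params,
        bse=bse,
        pvalues=pvals,
        re_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
        loglik=float(res.llf),
        method="REML" if reml else "ML",
        n_obs=len(y),
        n_groups=int(n_groups),
        converged=bool(res.converged),
    )


def vif(table: pd.DataFrame, predictors: Sequence[str]) -> dict[str, float]:
    """Variance inflation factor of each predictor.

    VIF_j = 1 / (1 - R²_j) where R²_j is from an ordinary least-squares
    regression (with intercept) of predictor j on the remaining
    predictors. Perfect collinearity is reported as ``inf``; a
    zero-variance predictor is a hard error.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    for p in predictors:
        if np.ptp(table[p].to_numpy(dtype=float)) == 0:
            raise ValueError(f"predictor {p!r} has zero variance")
    out: dict[str, float] = {}
    for p in predictors:
        others = [q for q in predictors if q != p]
        X = sm.add_constant(table[others].to_numpy(dtype=float))
        r2 = sm.OLS(table[p].to_numpy(dtype=float), X).fit().rsquared
        out[p] = float("inf") if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def likelihood_ratio_test(
    full: "LMMFit | float",
    reduced: "LMMFit | float",
    df: int | None = None,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested models: 2*(llf_full - llf_reduced).

    Accepts two ML fits (nesting and comparability are checked, df is the
    difference in fixed-effect count) or two raw log-likelihoods with an
    explicit ``df``. Returns (chi_square, df, upper-tail p). A negative
    statistic (optimizer failure) is floored at 0 with a warning.
    """
    if isinstance(full, LMMFit) and isinstance(reduced, LMMFit):
        full_terms = set(full.predictors)
        red_terms = set(reduced.predictors)
        if not red_terms < full_terms:
            raise ValueError(
                "reduced model's fixed effects must be a strict subset of the full model's"
            )
        if full.response != reduced.response or full.n_obs != reduced.n_obs:
            raise ValueError("models must be fit to the same data")
        # "exact" (noiseless closed-form) fits are the common limit of both
        # criteria and are accepted wherever ML is required
        if full.method not in ("ML", "exact") or reduced.method not in ("ML", "exact"):
            raise ValueError(
                "likelihood-ratio comparison requires both models refit by "
                f"maximum likelihood (got {full.method!r} vs {reduced.method!r})"
            )
        ll_full, ll_red = full.loglik, reduced.loglik
        df = len(full_terms) - len(red_terms)
    else:
        if isinstance(full, LMMFit) or isinstance(reduced, LMMFit):
            raise TypeError("pass two fits or two log-likelihoods, not a mixture")
        if df is None:
            raise ValueError("df is required when passing raw log-likelihoods")
        ll_full, ll_red = float(full), float(reduced)
    chi2 = 2.0 * (ll_full - ll_red)
    if chi2 < 0:
        warnings.warn(
            f"negative LRT statistic ({chi2:.3g}) floored at 0; "
            "likely an optimizer failure in one fit"
        )
        chi2 = 0.0
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return float(chi2), int(df), p


def lrt_drop_predictor(
    table: pd.DataFrame, response: str, drop: str = "mgs_f"
) -> tuple[float, int, float]:
    """LRT of the full model against the model without one predictor.

    Both models are refit by plain maximum likelihood on the same table.
    """
    if drop not in PREDICTORS:
        raise ValueError(f"unknown predictor {drop!r}")
    full = fit_lmm(table, response, PREDICTORS, reml=False)
    reduced = fit_lmm(
        table, response, [p for p in PREDICTORS if p != drop], reml=False
    )
    return likelihood_ratio_test(full, reduced)


def marginal_line(
    fit: "LMMFit | Mapping[str, float]",
    vary: str,
    held: Mapping[str, float],
) -> MarginalLine:
    """Marginal regression line in one predictor, others held fixed.

    ``fit`` is a fitted model or a plain coefficient mapping keyed by
    ``intercept`` and predictor names. The line's slope is the coefficient
    of ``vary``; its intercept is the model intercept plus the held
    covariates' contributions. Every predictor other than ``vary`` must
    appear in ``held``.
    """
    if isinstance(fit, LMMFit):
        coefs = fit.params
        predictors = fit.predictors
    else:
        coefs = dict(fit)
        predictors = [k for k in coefs if k != "intercept"]
    if vary not in predictors:
        raise ValueError(f"{vary!r} is not a predictor of this fit")
    missing = [p for p in predictors if p != vary and p not in held]
    if missing:
        raise ValueError(f"held values missing for predictor(s) {missing}")
    intercept = coefs["intercept"] + sum(
        held[p] * coefs[p] for p in predictors if p != vary
    )
    return MarginalLine(
        vary=vary,
        slope=float(coefs[vary]),
        intercept=float(intercept),
        held={p: float(held[p]) for p in predictors if p != vary},
    )


def sign_stability(
    table: pd.DataFrame, response: str, predictors: Sequence[str] = PREDICTORS
) -> dict[str, bool]:
    """Do coefficient signs agree between single- and multi-predictor fits?

    A supporting collinearity diagnostic: for each predictor, compare the
    sign of its coefficient in a single-predictor mixed model against its
    sign in the full model. Stable signs argue against harmful
    collinearity.
    """
    full = fit_lmm(table, response, predictors)
    out: dict[str, bool] = {}
    for p in predictors:
        single = fit_lmm(table, response, [p])
        out[p] = math.copysign(1, single.params[p]) == math.copysign(
            1, full.params[p]
        )
    return out
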