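"""Condition-level inferential summaries.

All models contrast the three between-dyad conditions with treatment
coding and Low iconicity as the default reference level:

* ``fit_condition_lm`` — OLS on a per-dyad measure (success index,
  accuracy, or game length) against condition.
* ``fit_stability_lmm`` — linear mixed model on successive-signal
  distances with crossed random intercepts for dyad and referent (REML,
  Satterthwaite degrees of freedom).
* ``fit_round_glmms`` — the round-by-round pair: a binomial GLMM on
  "any signal established" and a negative-binomial GLMM on the non-zero
  established counts, each with a scaled-round × condition interaction
  and dyad random intercepts.

Every fit returns a *coefficient table*: a DataFrame with columns
``term, estimate, se, stat, df, p`` (``df`` is NaN for z-based tests)
and model-level r² values in ``DataFrame.attrs``.  The mixed models are
fitted with R's lme4/lmerTest and glmmTMB through a subprocess bridge;
non-convergence is reported via warnings and the table's attrs, never
swallowed.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from ._rbridge import run_r

__all__ = [
    "fit_condition_lm",
    "fit_factorial_lm",
    "fit_stability_lmm",
    "fit_round_glmms",
    "get_term",
]

COEF_COLUMNS = ["term", "estimate", "se", "stat", "df", "p"]


def _clean_terms(terms: Iterable[str], factors: Mapping[str, Iterable[str]]) -> list:
    """Normalize term names to ``col[T.level]`` across backends.

    statsmodels emits ``C(col, Treatment(reference='x'))[T.level]`` and R
    emits ``collevel``; both are mapped to ``col[T.level]`` so downstream
    code can address contrasts uniformly.
    """
    out = []
    for t in terms:
        t = re.sub(r"C\(([^,)]+),\s*Treatment\([^)]*\)\)", r"\1", t)
        for col, levels in factors.items():
            for lev in levels:
                t = re.sub(rf"(?<![\w.\]]){re.escape(col)}{re.escape(str(lev))}(?![\w])",
                           f"{col}[T.{lev}]", t)
        t = t.replace("(Intercept)", "Intercept")
        out.append(t)
    return out


def get_term(table: pd.DataFrame, pattern: str) -> pd.Series:
    """Return the coefficient row named exactly ``pattern``, or — failing
    that — the single row whose term contains it."""
    exact = table[table["term"] == pattern]
    if len(exact) == 1:
        return exact.iloc[0]
    hit = table[table["term"].str.contains(pattern, regex=False)]
    if len(hit) != 1:
        raise KeyError(f"pattern {pattern!r} matched {len(hit)} terms: {list(table['term'])}")
    return hit.iloc[0]


def _ols_table(fit, factors: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "term": _clean_terms(fit.params.index, factors),
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "stat": fit.tvalues.to_numpy(),
            "df": float(fit.df_resid),
            "p": fit.pvalues.to_numpy(),
        }
    )
    table.attrs["r2"] = float(fit.rsquared)
    return table


def fit_condition_lm(
    per_dyad_table: pd.DataFrame,
    dv: str,
    reference: str = "low",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """OLS of a per-dyad measure on condition (treatment coding).

    ``dv`` is typically ``success_index``, ``accuracy`` or
    ``game_length_s``.  The reference level is configurable so contrasts
    can be read against either Low or High iconicity.
    """
    levels = sorted(per_dyad_table[condition_col].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("degenerate design: need >= 2 conditions")
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among conditions {levels}")
    formula = f"{dv} ~ C({condition_col}, Treatment(reference='{reference}'))"
    fit = smf.ols(formula, data=per_dyad_table).fit()
    return _ols_table(fit, {condition_col: levels})


def fit_factorial_lm(
    table: pd.DataFrame,
    dv: str,
    factors: Mapping[str, str],
) -> pd.DataFrame:
    """OLS with fully crossed treatment-coded factors and interactions.

    ``factors`` maps each factor column to its reference level; used for
    the follow-up experiment's signal-type × log 2 × 2 design.
    """
    if not factors:
        raise ValueError("need at least one factor")
    parts = [
        f"C({col}, Treatment(reference='{ref}'))" for col, ref in factors.items()
    ]
    formula = f"{dv} ~ " + " * ".join(parts)
    fit = smf.ols(formula, data=table).fit()
    levels = {col: sorted(table[col].astype(str).unique()) for col in factors}
    return _ols_table(fit, levels)


_LMM_SCRIPT = """
d <- tbl("data")
d$condition <- stats::relevel(factor(d$condition), ref = par$reference)
m <- lmer(distance ~ condition + (1 | dyad_id) + (1 | referent),
          data = d, REML = TRUE)
co <- as.data.frame(summary(m)$coefficients)
names(co) <- c("estimate", "se", "df", "stat", "p")
co$term <- rownames(co)
vc <- as.data.frame(lme4::VarCorr(m))
var_rand <- sum(vc$vcov[vc$grp != "Residual"])
var_resid <- sum(vc$vcov[vc$grp == "Residual"])
var_fixed <- stats::var(as.vector(stats::predict(m, re.form = NA)))
denom <- var_fixed + var_rand + var_resid
result <- list(coef = co,
               r2_marginal = var_fixed / denom,
               r2_conditional = (var_fixed + var_rand) / denom,
               messages = as.list(unlist(m@optinfo$conv$lme4$messages)))
"""


def fit_stability_lmm(
    stability_table: pd.DataFrame,
    reference: str = "low",
) -> pd.DataFrame:
    """Linear mixed model: distance ~ condition + (1|dyad) + (1|referent).

    REML fit via lmerTest with Satterthwaite degrees of freedom for the
    t tests.  attrs carry marginal r² (fixed effects only) and
    conditional r² (fixed + random), plus any convergence messages.
    """
    required = {"dyad_id", "referent", "condition", "distance"}
    missing = required - set(stability_table.columns)
    if missing:
        raise ValueError(f"stability table missing columns {sorted(missing)}")
    levels = sorted(stability_table["condition"].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("degenerate design: need >= 2 conditions")
    counts = stability_table.groupby("condition")["dyad_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 dyads per condition for the mixed model")
    res = run_r(
        _LMM_SCRIPT,
        tables={"data": stability_table[sorted(required)]},
        params={"reference": reference},
        libraries=("jsonlite", "lmerTest"),
    )
    coef = pd.DataFrame(res["coef"])
    coef["term"] = _clean_terms(coef["term"], {"condition": levels})
    table = coef[COEF_COLUMNS].copy()
    table.attrs["r2_marginal"] = float(res["r2_marginal"])
    table.attrs["r2_conditional"] = float(res["r2_conditional"])
    msgs = list(res.get("messages") or [])
    table.attrs["messages"] = msgs
    if msgs:
        warnings.warn(f"stability LMM convergence messages: {msgs}", RuntimeWarning)
    return table


_GLMM_SCRIPT = """
d <- tbl("data")
d$condition <- stats::relevel(factor(d$condition), ref = par$reference)
mb <- glmmTMB(presence ~ round_scaled * condition + (1 | dyad_id),
              family = binomial, data = d)
cb <- as.data.frame(summary(mb)$coefficients$cond)
names(cb) <- c("estimate", "se", "stat", "p")
cb$term <- rownames(cb)
nz <- d[d$s > 0, ]
mn <- glmmTMB(s ~ round_scaled * condition + (1 | dyad_id),
              family = nbinom2, data = nz)
cn <- as.data.frame(summary(mn)$coefficients$cond)
names(cn) <- c("estimate", "se", "stat", "p")
cn$term <- rownames(cn)
result <- list(binomial = cb, nbinom = cn,
               binomial_converged = isTRUE(mb$sdr$pdHess),
               nbinom_converged = isTRUE(mn$sdr$pdHess),
               nbinom_dispersion = sigma(mn))
"""


def fit_round_glmms(
    round_table: pd.DataFrame,
    reference: str = "low",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Round-by-round GLMM pair via glmmTMB.

    (a) binomial on ``presence`` (any referent established) and (b)
    negative-binomial (ML dispersion) on the non-zero established counts,
    both with scaled-round × condition interaction and dyad random
    intercepts.  Returns (binomial table, negative-binomial table); tests
    are Wald z, so ``df`` is NaN.
    """
    required = {"dyad_id", "condition", "round_scaled", "s", "presence"}
    missing = required - set(round_table.columns)
    if missing:
        raise ValueError(f"round table missing columns {sorted(missing)}")
    levels = sorted(round_table["condition"].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("degenerate design: need >= 2 conditions")
    if round_table["presence"].nunique() < 2:
        raise ValueError("degenerate response: presence column is constant")
    if (round_table["s"] > 0).sum() == 0:
        raise ValueError("degenerate response: no rounds with established signals")
    res = run_r(
        _GLMM_SCRIPT,
        tables={"data": round_table[sorted(required)]},
        params={"reference": reference},
        libraries=("jsonlite", "glmmTMB"),
    )
    tables = []
    for key, conv_key in (("binomial", "binomial_converged"), ("nbinom", "nbinom_converged")):
        coef = pd.DataFrame(res[key])
        coef["term"] = _clean_terms(coef["term"], {"condition": levels})
        coef["df"] = np.nan
        t = coef[COEF_COLUMNS].copy()
        t.attrs["converged"] = bool(res[conv_key])
        if not res[conv_key]:
            warnings.warn(f"{key} GLMM did not converge cleanly", RuntimeWarning)
        tables.append(t)
    tables[1].attrs["dispersion"] = float(res["nbinom_dispersion"])
    return tables[0], tables[1]
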