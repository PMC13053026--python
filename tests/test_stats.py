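"""Condition-contrast models: OLS, stability LMM, round-by-round GLMMs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from signalgame.stats import (
    fit_condition_lm,
    fit_factorial_lm,
    fit_round_glmms,
    fit_stability_lmm,
    get_term,
)

CONDS = ["high", "low", "one_sided"]


def dyad_table(means, n=12, sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for cond in CONDS:
        for i in range(n):
            rows.append({
                "dyad_id": f"{cond}_{i}",
                "condition": cond,
                "success_index": means[cond] + sd * rng.standard_normal(),
            })
    return pd.DataFrame(rows)


def test_constant_dv_gives_zero_contrasts():
    tab = fit_condition_lm(dyad_table({c: 0.4 for c in CONDS}), "success_index")
    for level in ("high", "one_sided"):
        assert get_term(tab, f"[T.{level}]").estimate == pytest.approx(0.0, abs=1e-12)


def test_two_group_contrast_is_difference_of_means():
    df = dyad_table({"high": 0.7, "low": 0.2, "one_sided": 0.5}, n=10, sd=0.05, seed=1)
    df = df[df.condition != "one_sided"]
    tab = fit_condition_lm(df, "success_index", reference="low")
    m = df.groupby("condition")["success_index"].mean()
    assert get_term(tab, "[T.high]").estimate == pytest.approx(m["high"] - m["low"])


def test_reference_level_swap_negates_contrast():
    df = dyad_table({"high": 0.7, "low": 0.2, "one_sided": 0.5}, sd=0.1, seed=2)
    low_ref = fit_condition_lm(df, "success_index", reference="low")
    high_ref = fit_condition_lm(df, "success_index", reference="high")
    hv_low = get_term(low_ref, "[T.high]").estimate
    lv_high = get_term(high_ref, "[T.low]").estimate
    assert hv_low == pytest.approx(-lv_high)
    assert low_ref.attrs["r2"] == pytest.approx(high_ref.attrs["r2"])


def test_single_condition_is_degenerate():
    df = dyad_table({c: 0.4 for c in CONDS})
    with pytest.raises(ValueError):
        fit_condition_lm(df[df.condition == "low"], "success_index")
    with pytest.raises(ValueError):
        fit_condition_lm(df, "success_index", reference="medium")


def test_factorial_lm_recovers_cell_structure():
    rng = np.random.default_rng(3)
    rows = []
    for sig in ("color", "dot"):
        for log_p in ("log", "nolog"):
            base = {"color": 0.6, "dot": 0.3}[sig] + (0.05 if log_p == "log" else 0.0)
            for i in range(15):
                rows.append({"signal": sig, "log": log_p,
                             "success_index": base + 0.02 * rng.standard_normal()})
    df = pd.DataFrame(rows)
    tab = fit_factorial_lm(df, "success_index", {"signal": "dot", "log": "nolog"})
    assert get_term(tab, "signal[T.color]").estimate == pytest.approx(0.3, abs=0.03)
    inter = tab[tab.term.str.contains(":")]
    assert len(inter) == 1 and abs(inter.iloc[0].estimate) < 0.03  # additive cells


def _stability_table(effects, n_dyads=6, n_obs=40, dyad_sd=0.0, ref_sd=0.0,
                     resid_sd=0.02, seed=0):
    rng = np.random.default_rng(seed)
    referents = ["banana", "eggplant", "strawberry", "blueberry", "orange", "kiwi"]
    ref_re = {r: ref_sd * rng.standard_normal() for r in referents}
    rows = []
    for cond in CONDS:
        for d in range(n_dyads):
            dyad = f"{cond}_{d}"
            dre = dyad_sd * rng.standard_normal()
            for i in range(n_obs):
                r = referents[int(rng.integers(6))]
                rows.append({
                    "dyad_id": dyad, "condition": cond, "referent": r,
                    "distance": effects[cond] + dre + ref_re[r]
                    + resid_sd * rng.standard_normal(),
                })
    return pd.DataFrame(rows)


def test_lmm_reduces_to_ols_without_random_variance():
    """With zero injected dyad/referent variance the REML fit collapses to
    the OLS solution (dual-route check against statsmodels)."""
    df = _stability_table({"high": 0.05, "low": 0.13, "one_sided": 0.055}, seed=4)
    with pytest.warns(RuntimeWarning):  # boundary (singular) fit is expected
        lmm = fit_stability_lmm(df)
    ols = smf.ols("distance ~ C(condition, Treatment(reference='low'))", data=df).fit()
    for level, pat in (("high", "[T.high]"), ("one_sided", "[T.one_sided]")):
        ols_est = ols.params[f"C(condition, Treatment(reference='low'))[T.{level}]"]
        assert get_term(lmm, pat).estimate == pytest.approx(ols_est, abs=1e-4)
    # Satterthwaite df and p-values present and sane
    assert (lmm.df > 0).all() and ((lmm.p > 0) & (lmm.p <= 1)).all()
    assert 0 <= lmm.attrs["r2_marginal"] <= lmm.attrs["r2_conditional"] <= 1


def test_lmm_recovers_known_condition_effect():
    df = _stability_table(
        {"high": 0.05, "low": 0.13, "one_sided": 0.05},
        n_dyads=20, n_obs=30, dyad_sd=0.02, ref_sd=0.01, resid_sd=0.05, seed=5,
    )
    lmm = fit_stability_lmm(df)
    row = get_term(lmm, "[T.high]")
    assert abs(row.estimate - (-0.08)) < 2 * row.se
    assert row.p < 0.05


def test_lmm_requires_enough_structure():
    df = _stability_table({c: 0.1 for c in CONDS}, n_dyads=1)
    with pytest.raises(ValueError):
        fit_stability_lmm(df)
    with pytest.raises(ValueError):
        fit_stability_lmm(df.drop(columns=["referent"]))


def _round_table_sim(seed=0, n_dyads=10, n_rounds=60, cond_effect=2.0):
    """Parametric round-table generator: presence probability rises with
    round number; counts are larger in the high condition."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond in CONDS:
        bump = cond_effect if cond == "high" else 0.0
        for d in range(n_dyads):
            dyad = f"{cond}_{d}"
            dre = 0.3 * rng.standard_normal()
            for t in range(n_rounds):
                z = (t - n_rounds / 2) / (n_rounds / 4)
                logit = -0.5 + 1.0 * z + bump + dre
                presence = rng.random() < 1 / (1 + np.exp(-logit))
                s = 0
                if presence:
                    lam = np.exp(0.2 + 0.15 * z + 0.3 * (cond == "high"))
                    # gamma mixing makes the counts genuinely overdispersed
                    s = 1 + int(rng.poisson(lam * rng.gamma(2.0, 0.5)))
                rows.append({"dyad_id": dyad, "condition": cond,
                             "round_index": t + 1, "s": s, "presence": int(presence)})
    df = pd.DataFrame(rows)
    df["round_scaled"] = (df.round_index - df.round_index.mean()) / df.round_index.std(ddof=1)
    return df


def test_round_glmms_recover_signs():
    df = _round_table_sim(seed=6)
    binom, nbinom = fit_round_glmms(df)
    assert get_term(binom, "round_scaled").term == "round_scaled"
    assert get_term(binom, "round_scaled").estimate > 0       # presence rises with round
    assert get_term(binom, "condition[T.high]").estimate > 0  # high-iconicity head start
    assert get_term(binom, "condition[T.high]").p < 0.05
    nb_high = nbinom[nbinom.term == "condition[T.high]"].iloc[0]
    assert nb_high.estimate > 0 and nb_high.p < 0.05
    assert nbinom.attrs["dispersion"] > 0


def test_round_glmms_reject_degenerate_responses():
    df = _round_table_sim(seed=7)
    flat = df.copy()
    flat["presence"] = 0
    flat["s"] = 0
    with pytest.raises(ValueError):
        fit_round_glmms(flat)
    with pytest.raises(ValueError):
        fit_round_glmms(df.drop(columns=["s"]))
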