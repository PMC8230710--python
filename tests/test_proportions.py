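import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arsenspec.curves import REFERENCE_PROPORTION_CURVES, ProportionModel
from arsenspec.proportions import (
    bin_by_percentile,
    fit_adjusted_proportions,
    fit_proportion_model,
)
from arsenspec.synthetic import generate_proportion_observations

# --- percentile binning -----------------------------------------------------


def _profiles_from(h, props=None):
    df = pd.DataFrame({"has_icp": np.asarray(h, float)})
    if props is not None:
        for sp, vals in props.items():
            df[f"prop_{sp}"] = vals
    return df


def test_identity_binning():
    h = np.arange(1.0, 101.0)
    binned = bin_by_percentile(_profiles_from(h), n_bins=100)
    assert (binned["n"] == 1).all()
    np.testing.assert_allclose(binned["has_icp"], np.sort(h))


def test_pair_binning():
    h = [8, 1, 6, 3, 5, 4, 7, 2]
    binned = bin_by_percentile(_profiles_from(h), n_bins=4)
    np.testing.assert_allclose(binned["has_icp"], [1.5, 3.5, 5.5, 7.5])


def test_bin_sizes_and_count_conservation(profiles457):
    binned = bin_by_percentile(profiles457, n_bins=100)
    assert set(binned["n"]) <= {4, 5}
    assert binned["n"].sum() == len(profiles457)
    # remainder goes to the lowest sections
    sizes = binned["n"].to_numpy()
    assert (np.diff(sizes) <= 0).all()


def test_binning_order_invariance(rng):
    h = rng.lognormal(4, 0.8, size=457)
    a = bin_by_percentile(_profiles_from(h), 50)
    b = bin_by_percentile(_profiles_from(rng.permutation(h)), 50)
    pd.testing.assert_frame_equal(a, b)


def test_binning_requires_enough_profiles():
    with pytest.raises(ValueError):
        bin_by_percentile(_profiles_from([1.0, 2.0]), 4)


# --- curve fitting ----------------------------------------------------------


def binned_from_curve(model, h):
    clean = generate_proportion_observations(
        type(REFERENCE_PROPORTION_CURVES)(
            as3=model if model.species == "as3" else REFERENCE_PROPORTION_CURVES.as3,
            as5=model if model.species == "as5" else REFERENCE_PROPORTION_CURVES.as5,
            mma=model if model.species == "mma" else REFERENCE_PROPORTION_CURVES.mma,
        ),
        h,
        noise_sd=0.0,
    )
    sub = clean[clean.species == model.species]
    return pd.DataFrame(
        {"has_icp": sub.h.to_numpy(), f"prop_{model.species}": sub.proportion.to_numpy()}
    )


def test_noiseless_power_recovery():
    h = np.geomspace(5, 500, 60)
    binned = binned_from_curve(REFERENCE_PROPORTION_CURVES.as3, h)
    fit = fit_proportion_model(binned, "as3", "power")
    a, b = fit.coefficients
    assert a == pytest.approx(2.724, abs=1e-6)
    assert b == pytest.approx(0.529, abs=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


def test_noiseless_quadratic_recovery():
    h = np.linspace(10, 400, 40)
    binned = binned_from_curve(REFERENCE_PROPORTION_CURVES.mma, h)
    fit = fit_proportion_model(binned, "mma", "quadratic")
    c2, c1, c0 = fit.coefficients
    assert c2 == pytest.approx(0.0000645, rel=1e-8)
    assert c1 == pytest.approx(-0.0381, rel=1e-8)
    assert c0 == pytest.approx(6.773, rel=1e-8)
    assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)


def test_quadratic_exact_through_four_points():
    h = np.array([1.0, 2.0, 5.0, 9.0])
    y = 0.3 * h**2 - 1.1 * h + 4.0
    fit = fit_proportion_model(_profiles_from(h, {"as5": y}), "as5", "quadratic")
    np.testing.assert_allclose(fit.coefficients, (0.3, -1.1, 4.0), atol=1e-9)


def test_constant_proportions_degenerate_power():
    h = np.array([1.0, 10.0, 100.0])
    fit = fit_proportion_model(_profiles_from(h, {"as3": [4.0, 4.0, 4.0]}), "as3", "power")
    assert fit.coefficients == (4.0, 0.0)
    assert fit.r2 == 0.0


def test_power_recovery_under_noise(rng):
    """Gaussian 1-pp scatter around the power curve, 100 sections: the
    coefficients come back within a few percent."""
    errs = []
    for _ in range(20):
        h = np.exp(rng.uniform(np.log(5), np.log(500), 5000))
        y = 2.724 * h**-0.529 + rng.normal(0, 1.0, h.size)
        binned = bin_by_percentile(_profiles_from(h, {"as3": y}), 100)
        a, b = fit_proportion_model(binned, "as3", "power").coefficients
        errs.append(max(abs(a - 2.724) / 2.724, abs(b - 0.529) / 0.529))
    assert np.median(errs) < 0.10


def test_fit_domain_recorded():
    h = np.geomspace(5, 500, 30)
    binned = binned_from_curve(REFERENCE_PROPORTION_CURVES.as3, h)
    fit = fit_proportion_model(binned, "as3", "power")
    assert fit.fit_domain == (pytest.approx(5.0), pytest.approx(500.0))


# --- least-squares means ----------------------------------------------------


def lsm_oracle(df, factors, outcome, focal):
    """Normal-equations + prediction-averaging reference implementation with
    manual one-hot encoding (drop-first)."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    level_map = {}
    for f in factors:
        levels = sorted(df[f].unique())
        level_map[f] = levels
        for lv in levels[1:]:
            cols.append((df[f] == lv).to_numpy(float))
            names.append(f"{f}:{lv}")
    X = np.column_stack(cols)
    beta = np.linalg.solve(X.T @ X, X.T @ df[outcome].to_numpy(float))

    out = {}
    for lv in level_map[focal]:
        forced = df.copy()
        forced[focal] = lv
        cols_f = [np.ones(len(df))]
        for f in factors:
            for l2 in level_map[f][1:]:
                cols_f.append((forced[f] == l2).to_numpy(float))
        Xf = np.column_stack(cols_f)
        out[lv] = float((Xf @ beta).mean())
    return out


def make_design(rng, n=120, balanced=True):
    if balanced:
        a = np.repeat(["a1", "a2"], n // 2)
        b = np.tile(np.repeat(["b1", "b2"], n // 4), 2)
    else:
        a = rng.choice(["a1", "a2"], size=n, p=[0.7, 0.3])
        b = rng.choice(["b1", "b2", "b3"], size=n, p=[0.5, 0.3, 0.2])
    y = (
        10.0
        + 4.0 * (a == "a2")
        + 2.0 * (b == "b2")
        - 3.0 * (b == "b3")
        + rng.normal(0, 1.5, size=n)
    )
    return pd.DataFrame({"fa": a, "fb": b, "prop_mma": y})


def test_separated_groups_get_distinct_letters():
    df = pd.DataFrame({"g": ["x", "x", "y", "y"], "prop_mma": [10.0, 10.0, 20.0, 20.0]})
    res = fit_adjusted_proportions(df, ["g"], outcomes=("prop_mma",))
    t = res.table.set_index("level")
    assert t.loc["x", "prop_mma_lsm"] == pytest.approx(10.0)
    assert t.loc["y", "prop_mma_lsm"] == pytest.approx(20.0)
    assert t.loc["x", "prop_mma_letters"] != t.loc["y", "prop_mma_letters"]


def test_identical_groups_share_a_letter(rng):
    y = rng.normal(10, 1, size=40)
    df = pd.DataFrame({"g": np.tile(["x", "y"], 20), "prop_mma": np.repeat(y, 2)[:40]})
    df["prop_mma"] = np.concatenate([y[:20], y[:20]])
    df["g"] = np.repeat(["x", "y"], 20)
    res = fit_adjusted_proportions(df, ["g"], outcomes=("prop_mma",))
    t = res.table.set_index("level")
    assert t.loc["x", "prop_mma_lsm"] == pytest.approx(t.loc["y", "prop_mma_lsm"])
    assert set(t.loc["x", "prop_mma_letters"]) & set(t.loc["y", "prop_mma_letters"])


def test_balanced_design_lsm_equals_group_mean(rng):
    df = make_design(rng, balanced=True)
    res = fit_adjusted_proportions(df, ["fa", "fb"], outcomes=("prop_mma",))
    t = res.table.set_index(["factor", "level"])
    for lv, grp in df.groupby("fa"):
        assert t.loc[("fa", lv), "prop_mma_lsm"] == pytest.approx(
            grp["prop_mma"].mean(), abs=1e-9
        )


def test_unbalanced_design_matches_oracle(rng):
    df = make_design(rng, balanced=False)
    res = fit_adjusted_proportions(df, ["fa", "fb"], outcomes=("prop_mma",))
    t = res.table.set_index(["factor", "level"])
    for focal in ("fa", "fb"):
        ref = lsm_oracle(df, ["fa", "fb"], "prop_mma", focal)
        for lv, val in ref.items():
            assert t.loc[(focal, lv), "prop_mma_lsm"] == pytest.approx(val, abs=1e-8)


def test_letters_agree_with_exhaustive_bonferroni(rng):
    # four levels with two clear clusters
    levels = np.repeat(["l1", "l2", "l3", "l4"], 30)
    y = np.concatenate(
        [
            rng.normal(5, 1, 30),
            rng.normal(5.3, 1, 30),
            rng.normal(12, 1, 30),
            rng.normal(12.4, 1, 30),
        ]
    )
    df = pd.DataFrame({"g": levels, "prop_mma": y})
    res = fit_adjusted_proportions(df, ["g"], outcomes=("prop_mma",))
    t = res.table.set_index("level")

    # exhaustive pairwise Welch-free t-tests on the same linear model
    import statsmodels.formula.api as smf

    fitm = smf.ols("prop_mma ~ C(g)", data=df).fit()
    mse = fitm.mse_resid
    dfr = fitm.df_resid
    m = 6
    for a, b in itertools.combinations(["l1", "l2", "l3", "l4"], 2):
        ya, yb = df[df.g == a]["prop_mma"], df[df.g == b]["prop_mma"]
        se = np.sqrt(mse * (1 / len(ya) + 1 / len(yb)))
        p_adj = min(1.0, 2 * stats.t.sf(abs(ya.mean() - yb.mean()) / se, dfr) * m)
        share = bool(set(t.loc[a, "prop_mma_letters"]) & set(t.loc[b, "prop_mma_letters"]))
        assert share == (p_adj >= 0.05)


def test_overall_factor_p_is_partial_f(rng):
    df = make_design(rng, balanced=False)
    res = fit_adjusted_proportions(df, ["fa", "fb"], outcomes=("prop_mma",))
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    fitm = smf.ols("prop_mma ~ C(fa) + C(fb)", data=df).fit()
    ref = anova_lm(fitm, typ=2)
    assert res.p_values.loc["fa", "prop_mma"] == pytest.approx(
        ref.loc["C(fa)", "PR(>F)"], abs=1e-10
    )


def test_ci_symmetric_about_lsm(rng):
    df = make_design(rng, balanced=False)
    res = fit_adjusted_proportions(df, ["fa", "fb"], outcomes=("prop_mma",))
    t = res.table
    np.testing.assert_allclose(
        t["prop_mma_lsm"] - t["prop_mma_lo"], t["prop_mma_hi"] - t["prop_mma_lsm"],
        rtol=1e-10,
    )


def test_singular_design_raises():
    # fb is a copy of fa → aliased columns
    df = pd.DataFrame(
        {"fa": ["x", "x", "y", "y"], "fb": ["u", "u", "v", "v"], "prop_mma": [1.0, 2, 3, 4]}
    )
    with pytest.raises(ValueError, match="singular"):
        fit_adjusted_proportions(df, ["fa", "fb"], outcomes=("prop_mma",))


def test_single_level_factor_rejected():
    df = pd.DataFrame({"g": ["x", "x"], "prop_mma": [1.0, 2.0]})
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_adjusted_proportions(df, ["g"], outcomes=("prop_mma",))
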