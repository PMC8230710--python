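import numpy as np
import pytest

from arsenspec.agreement import (
    additive_bias_correction,
    agreement_analysis,
    lin_ccc,
    ols_fit,
)
from arsenspec.preprocess import build_profiles, filter_by_creatinine
from arsenspec.synthetic import CohortParams, generate_cohort


def ccc_direct(x, y, ddof=0):
    """Straight transcription of the concordance formula, kept separate from
    the library implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx2 = np.sum((x - x.mean()) ** 2) / (n - ddof)
    sy2 = np.sum((y - y.mean()) ** 2) / (n - ddof)
    sxy = np.sum((x - x.mean()) * (y - y.mean())) / (n - ddof)
    return 2 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)


def ols_normal_equations(x, y):
    X = np.column_stack([np.ones_like(x), x])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    return coef[1], coef[0]


# --- concordance ------------------------------------------------------------


def test_ccc_hand_value():
    # s_x²=s_y²=s_xy=2/3, mean gap 3 → 2·(2/3)/(4/3+9) = 4/31
    assert lin_ccc([0, 1, 2], [3, 4, 5]) == pytest.approx(4 / 31, abs=1e-15)


def test_ccc_perfect_concordance_is_exactly_one(rng):
    x = rng.normal(size=100)
    assert lin_ccc(x, x.copy()) == 1.0


def test_ccc_symmetry_and_attenuation(rng):
    for _ in range(1000):
        n = int(rng.integers(2, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n) * rng.uniform(0.5, 2) + rng.uniform(-3, 3)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        c = lin_ccc(x, y)
        assert c == pytest.approx(lin_ccc(y, x), abs=1e-12)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(c) <= abs(r) + 1e-12


def test_ccc_near_zero_for_independent_series(rng):
    x, y = rng.normal(size=10_000), rng.normal(size=10_000)
    assert abs(lin_ccc(x, y)) < 0.05


def test_ccc_moment_convention_option(rng):
    x, y = rng.normal(size=25), rng.normal(size=25)
    assert lin_ccc(x, y) == pytest.approx(ccc_direct(x, y, ddof=0), abs=1e-14)
    assert lin_ccc(x, y, sample_moments=True) == pytest.approx(
        ccc_direct(x, y, ddof=1), abs=1e-14
    )


def test_ccc_degenerate_inputs():
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(lin_ccc([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))
    with pytest.raises(ValueError):
        lin_ccc([1.0], [2.0])


# --- calibration line -------------------------------------------------------


def test_ols_exact_line_with_offset():
    slope, intercept, r2 = ols_fit([0.0, 1.0, 2.0], [18.0, 19.0, 20.0])
    assert slope == pytest.approx(1.0, abs=1e-12)
    assert intercept == pytest.approx(18.0, abs=1e-12)
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_ols_identity():
    x = np.arange(5.0)
    slope, intercept, r2 = ols_fit(x, x)
    assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0), abs=1e-14)


def test_ols_matches_normal_equations(rng):
    x = rng.uniform(0, 100, size=50)
    y = 3.0 + 0.7 * x + rng.normal(0, 5, size=50)
    slope, intercept, _ = ols_fit(x, y)
    ref_slope, ref_intercept = ols_normal_equations(x, y)
    assert slope == pytest.approx(ref_slope, abs=1e-10)
    assert intercept == pytest.approx(ref_intercept, abs=1e-10)


def test_ols_translation_property(rng):
    x = rng.uniform(0, 50, size=80)
    y = rng.normal(10, 4, size=80) + 0.5 * x
    slope, intercept, _ = ols_fit(x, y)
    for c in (-17.0, 3.5, 120.0):
        s2, i2, _ = ols_fit(x + c, y)
        assert s2 == pytest.approx(slope, abs=1e-10)
        assert i2 == pytest.approx(intercept - slope * c, abs=1e-8)


def test_ols_rejects_constant_x():
    with pytest.raises(ValueError, match="constant"):
        ols_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# --- bias correction --------------------------------------------------------


def test_pure_offset_correction(rng):
    x = rng.uniform(10, 100, size=40)
    y = x + 5.0
    shift, corrected = additive_bias_correction(x, y)
    assert shift == pytest.approx(5.0, abs=1e-9)
    np.testing.assert_allclose(corrected, y, rtol=1e-12)
    assert lin_ccc(corrected, y) == pytest.approx(1.0, abs=1e-12)


def test_no_bias_correction_is_identity(rng):
    x = rng.uniform(10, 100, size=40)
    shift, corrected = additive_bias_correction(x, x.copy())
    assert shift == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(corrected, x, atol=1e-9)


def test_generator_round_trip_recovers_offset():
    # computed on the stored truth values: LOD/2 substitution downstream
    # perturbs censored low-end species and would blur the exact identity
    params = CohortParams(
        n_subjects=300, seed=9, prop_noise_sd=0.0, assay_noise_cv=0.0,
        frac_high_stratum=0.0, covariate_effects={},
    )
    records = generate_cohort(params)
    icp = np.array([(r.as3 + r.as5 + r.mma + r.dma) / r.creatinine for r in records])
    aas = np.array([r.has_aas / r.creatinine for r in records])
    keep = aas > 0  # readings under the offset floor at zero
    shift, _ = additive_bias_correction(aas[keep], icp[keep])
    assert shift == pytest.approx(18.0, abs=1e-6)


# --- composite analysis -----------------------------------------------------


def test_translation_identity_of_full_analysis(rng):
    x = rng.uniform(5, 300, size=200)
    y = 18.0 + 1.03 * x
    res = agreement_analysis(x, y)
    assert res.slope == pytest.approx(1.03, abs=1e-10)
    assert res.intercept == pytest.approx(18.0, abs=1e-8)
    # after adding the intercept back to x, the new intercept is 18·(1−1.03)
    assert res.corrected_slope == pytest.approx(res.slope, abs=1e-10)
    assert res.corrected_intercept == pytest.approx(18.0 - 1.03 * 18.0, abs=1e-8)


def test_offset_removal_improves_concordance(profiles457):
    res = agreement_analysis(
        profiles457["has_aas_cr"].to_numpy(), profiles457["has_icp"].to_numpy()
    )
    assert res.corrected_ccc > res.ccc
    assert abs(res.ccc) <= abs(res.pearson_r)


def test_intercept_recovery_across_replicates():
    """At low assay noise the calibration intercept recovers the generator's
    assay offset; regression dilution from noise on the regressor stays
    negligible at cv = 0.02."""
    intercepts = []
    for s in range(200):
        params = CohortParams(n_subjects=457, seed=5000 + s, assay_noise_cv=0.02)
        profiles = build_profiles(filter_by_creatinine(generate_cohort(params))[0])
        _, intercept, _ = ols_fit(
            profiles["has_aas_cr"].to_numpy(), profiles["has_icp"].to_numpy()
        )
        intercepts.append(intercept)
    assert np.mean(intercepts) == pytest.approx(18.0, rel=0.02)
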