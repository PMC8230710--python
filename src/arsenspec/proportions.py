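"""Species-proportion modelling.

Two complementary views of how the speciation profile shifts with the total
hazardous-arsenic concentration:

1. **Covariate-adjusted least-squares means** (estimated marginal means) of
   each proportion outcome across the levels of questionnaire factors, with
   an overall partial F-test per factor and Bonferroni-corrected pairwise
   contrasts summarized as a compact letter display.
2. **Percentile-section curves**: subjects are ranked by the speciated
   total, split into equal-count sections, and the per-section mean
   proportion is fit against the per-section mean total with a power decay
   (AsIII) or a quadratic (AsV, MMA, DMA).

The least-squares mean of a factor level is defined by prediction
averaging: every subject's covariate vector is kept as observed except for
the focal factor, which is set to the level in question; the LSM is the
mean model prediction over the cohort.  In a balanced orthogonal design
this reduces to the raw group mean.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.formula.api as smf

from .curves import (  # noqa: F401  (re-exported: the curve types live with their fits)
    DEFAULT_PROPORTION_CURVES,
    EvaluatedProportion,
    ModelSet,
    ProportionModel,
    evaluate_proportion_model,
)

__all__ = [
    "ProportionModel",
    "ModelSet",
    "evaluate_proportion_model",
    "AdjustedProportionTable",
    "fit_adjusted_proportions",
    "bin_by_percentile",
    "fit_proportion_model",
    "DEFAULT_OUTCOMES",
]

#: proportion outcomes reported per factor level, in table order
DEFAULT_OUTCOMES = (
    "prop_as3",
    "prop_as5",
    "prop_ias",
    "prop_mma",
    "prop_dma",
    "prop_oas",
    "prop_non_dma",
)


# ---------------------------------------------------------------------------
# Least-squares means


@dataclass(frozen=True)
class AdjustedProportionTable:
    """LSM table: one row per (factor, level), one column block per outcome.

    ``table`` columns: factor, level, n, percent, then per outcome
    ``{outcome}_lsm``, ``{outcome}_lo``, ``{outcome}_hi``, ``{outcome}_letters``.
    ``p_values`` is indexed by factor with one column per outcome (overall
    partial F-test).  CIs are symmetric about the LSM on the model scale;
    rendering may truncate negative bounds at zero for display.
    """

    table: pd.DataFrame
    p_values: pd.DataFrame
    alpha: float


def _compact_letters(levels: list[str], lsm: dict[str, float], sig: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``sig`` holds unordered level pairs that are significantly different
    after multiplicity correction.  Levels sort by descending LSM (ties by
    input order); every non-significant pair shares at least one letter and
    no significant pair shares any.
    """
    order = sorted(levels, key=lambda lv: (-lsm[lv], levels.index(lv)))
    sets: list[set[str]] = [set(order)]
    for pair in sig:
        a, b = tuple(pair)
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop any set contained in another
        sets = [
            s
            for s in new_sets
            if s and not any(s < t for t in new_sets)
        ]
        # deduplicate
        uniq: list[set[str]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    # letter order follows the best (highest-LSM) member of each set
    sets.sort(key=lambda s: min(order.index(lv) for lv in s))
    letters = {lv: "" for lv in levels}
    for letter, s in zip(itertools.cycle(string.ascii_lowercase), sets):
        for lv in order:
            if lv in s:
                letters[lv] += letter
    return letters


def fit_adjusted_proportions(
    profiles: pd.DataFrame,
    factors: list[str],
    alpha: float = 0.05,
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES,
) -> AdjustedProportionTable:
    """Covariate-adjusted proportion means per factor level.

    For each outcome an additive linear model on all factors is fit at
    once; LSMs come from prediction averaging (see module docstring), CIs
    from the t-distribution on the residual degrees of freedom, the overall
    factor p-value from the partial F-test of the factor's coefficients,
    and letters from Bonferroni-corrected pairwise LSM contrasts (m = pairs
    within the factor).
    """
    if not factors:
        raise ValueError("at least one factor required")
    df = profiles.copy()
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor {f!r} not in profiles")
        df[f] = df[f].astype(str).replace({"": "missing", "nan": "missing"})
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")

    rhs = " + ".join(f"C({f})" for f in factors)
    n_total = len(df)
    rows: dict[tuple[str, str], dict] = {}
    p_rows: dict[str, dict] = {f: {} for f in factors}

    for f in factors:
        for level, cnt in df[f].value_counts().items():
            rows[(f, str(level))] = {
                "factor": f,
                "level": str(level),
                "n": int(cnt),
                "percent": 100.0 * cnt / n_total,
            }

    for outcome in outcomes:
        model = smf.ols(f"{outcome} ~ {rhs}", data=df).fit()
        exog = model.model.exog
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise ValueError(
                "singular design matrix (aliased levels) for outcome "
                f"{outcome!r}; columns: {model.model.exog_names}"
            )
        design_info = model.model.data.design_info
        beta = model.params.to_numpy()
        cov = model.cov_params().to_numpy()
        df_resid = model.df_resid
        t_mult = stats.t.ppf(1.0 - alpha / 2.0, df_resid)

        from patsy import build_design_matrices

        for f in factors:
            levels = sorted(df[f].unique())
            # ℓ-vector per level: mean design row with the factor forced
            ell = {}
            for lv in levels:
                forced = df.copy()
                forced[f] = lv
                (X,) = build_design_matrices([design_info], forced)
                ell[lv] = np.asarray(X).mean(axis=0)
            lsm = {lv: float(ell[lv] @ beta) for lv in levels}
            se = {lv: float(np.sqrt(ell[lv] @ cov @ ell[lv])) for lv in levels}
            # Bonferroni pairwise contrasts
            pairs = list(itertools.combinations(levels, 2))
            m = len(pairs)
            sig: set[frozenset] = set()
            for a, b in pairs:
                c = ell[a] - ell[b]
                var_c = float(c @ cov @ c)
                if var_c <= 0:
                    # zero residual variance: any non-zero difference is exact
                    if abs(lsm[a] - lsm[b]) > 1e-12:
                        sig.add(frozenset((a, b)))
                    continue
                t_stat = (lsm[a] - lsm[b]) / np.sqrt(var_c)
                p_adj = min(1.0, 2.0 * stats.t.sf(abs(t_stat), df_resid) * m)
                if p_adj < alpha:
                    sig.add(frozenset((a, b)))
            letters = _compact_letters(levels, lsm, sig)
            for lv in levels:
                row = rows[(f, lv)]
                row[f"{outcome}_lsm"] = lsm[lv]
                row[f"{outcome}_lo"] = lsm[lv] - t_mult * se[lv]
                row[f"{outcome}_hi"] = lsm[lv] + t_mult * se[lv]
                row[f"{outcome}_letters"] = letters[lv]
            # overall partial F-test on the factor's coefficients
            term = f"C({f})"
            slices = design_info.term_name_slices
            sl = slices[term]
            R = np.zeros((sl.stop - sl.start, len(beta)))
            for i, j in enumerate(range(sl.start, sl.stop)):
                R[i, j] = 1.0
            ftest = model.f_test(R)
            p_rows[f][outcome] = float(ftest.pvalue)

    table = pd.DataFrame(list(rows.values())).sort_values(
        ["factor", "level"], kind="stable"
    ).reset_index(drop=True)
    p_values = pd.DataFrame(p_rows).T
    p_values.index.name = "factor"
    return AdjustedProportionTable(table=table, p_values=p_values, alpha=alpha)


# ---------------------------------------------------------------------------
# Percentile-section curves


def bin_by_percentile(profiles: pd.DataFrame, n_bins: int = 100) -> pd.DataFrame:
    """Equal-count sections of the cohort ranked by the speciated total.

    Subjects are sorted by ``has_icp`` (stable, so input order breaks ties)
    and split into ``n_bins`` contiguous sections; when n is not divisible
    the remainder is spread over the lowest sections.  Returns per-section
    arithmetic means of the total and of each species proportion.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(profiles)
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} profiles, got {n}")
    order = profiles["has_icp"].to_numpy(dtype=float).argsort(kind="stable")
    ranked = profiles.iloc[order]
    chunks = np.array_split(np.arange(n), n_bins)
    rows = []
    for b, idx in enumerate(chunks):
        grp = ranked.iloc[idx]
        row = {"bin": b, "n": len(grp), "has_icp": float(grp["has_icp"].mean())}
        for sp in ("as3", "as5", "mma", "dma"):
            col = f"prop_{sp}"
            if col in grp.columns:
                row[col] = float(grp[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _r2_pair(y: np.ndarray, fitted: np.ndarray, n_params: int) -> tuple[float, float]:
    sst = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - fitted) ** 2).sum())
    r2 = 0.0 if sst == 0.0 else 1.0 - sse / sst
    n = y.size
    # adjusted R²: 1 − (1−R²)(n−1)/(n−p−1) with p = predictors excl. intercept
    p_pred = n_params - 1
    if n - p_pred - 1 <= 0:
        return r2, r2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p_pred - 1)
    return r2, adj


def fit_proportion_model(
    binned: pd.DataFrame,
    species: str,
    form: str,
    max_iter: int = 10000,
) -> ProportionModel:
    """Fit a proportion-versus-total curve to percentile-section means.

    Quadratic curves are fit by linear least squares on (h², h, 1).  Power
    curves ``a·h^(-b)`` are fit by nonlinear least squares initialized from
    the log–log linear fit (using the strictly positive observations); a
    constant outcome short-circuits to ``(a=constant, b=0)`` with R² = 0 by
    convention.  Non-convergence raises with the log–log fallback attached
    to the exception.
    """
    col = f"prop_{species}"
    h = binned["has_icp"].to_numpy(dtype=float)
    y = binned[col].to_numpy(dtype=float)
    domain = (float(h.min()), float(h.max()))
    if form == "quadratic":
        if h.size < 4:
            raise ValueError("quadratic fit needs at least 4 sections")
        X = np.column_stack([h**2, h, np.ones_like(h)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        r2, adj = _r2_pair(y, fitted, n_params=3)
        return ProportionModel(species, "quadratic", tuple(map(float, coef)), r2, adj, domain)
    if form != "power":
        raise ValueError(f"unknown form {form!r}")
    if h.size < 3:
        raise ValueError("power fit needs at least 3 sections")
    if np.any(h <= 0):
        raise ValueError("power fit requires h > 0")
    if np.allclose(y, y[0]):
        return ProportionModel(species, "power", (float(y[0]), 0.0), 0.0, 0.0, domain)
    pos = y > 0
    if pos.sum() >= 2:
        b0, loga0 = np.polyfit(np.log(h[pos]), np.log(y[pos]), 1)
        a_init, b_init = float(np.exp(loga0)), float(-b0)
    else:
        a_init, b_init = max(float(y.mean()), 1e-6), 0.5

    def power(hh, a, b):
        return a * hh ** (-b)

    try:
        coef, _ = optimize.curve_fit(
            power, h, y, p0=(a_init, b_init), maxfev=max_iter
        )
    except RuntimeError as err:  # iteration cap
        err.fallback = (a_init, b_init)  # type: ignore[attr-defined]
        raise
    fitted = power(h, *coef)
    r2, adj = _r2_pair(y, fitted, n_params=2)
    return ProportionModel(species, "power", (float(coef[0]), float(coef[1])), r2, adj, domain)
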