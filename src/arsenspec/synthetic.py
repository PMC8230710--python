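"""Synthetic cohort generator for urinary arsenic biomonitoring analyses.

Emulates the statistical structure of a mine-area biomonitoring cohort in
which each subject's urine carries four arsenic species — arsenite (AsIII),
arsenate (AsV), monomethylarsinic acid (MMA) and dimethylarsenic acid (DMA)
— measured individually by a speciating assay (HPLC-ICP-MS) and jointly, as
a single hazardous-arsenic sum, by a cheaper assay (HG-AAS).  The generator
reproduces the features the downstream analysis leans on:

* a DMA-dominated, log-normal speciation profile (DMA share > 90% for most
  subjects);
* AsV and MMA shares that fall as the total concentration rises, and an
  AsIII share with a power-law decay, via configurable proportion curves;
* an additive systematic offset between the two assays (speciated sum
  higher than the summed assay, default 18 µg/g-cr) plus multiplicative
  measurement noise on the summed assay;
* left-censoring below per-species limits of detection;
* a rare high-exposure stratum with a large (default 50×) multiplier on
  the inorganic species, mimicking a contaminated-drinking-water site.

Totals are drawn on the creatinine-adjusted scale (µg/g-cr), the scale on
which the analysis operates, and converted to raw µg/L readings via each
subject's sampled urinary creatinine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import ModelSet, ProportionModel, evaluate_proportion_model
from .preprocess import LODConfig

__all__ = [
    "DEFAULT_GENERATOR_CURVES",
    "CohortParams",
    "SubjectRecord",
    "generate_cohort",
    "generate_proportion_observations",
    "cohort_to_frame",
    "write_cohort_csv",
]

#: sampling frequencies for the categorical covariates, shaped after a
#: rural Korean mine-area cohort (older, majority-female, substantial
#: groundwater use); "missing" is an explicit level where questionnaires
#: realistically go unanswered.
COVARIATE_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.41, "female": 0.59},
    "age_group": {"<=59": 0.175, "60-69": 0.316, "70-79": 0.351, ">=80": 0.158},
    "residence_group": {"<=20": 0.188, "21-40": 0.158, "41-60": 0.342, ">=61": 0.310, "missing": 0.002},
    "water_source": {"groundwater": 0.59, "tap": 0.41},
    "seafood_last_week": {"yes": 0.59, "no": 0.125, "missing": 0.285},
    "distance_group": {"<0.5": 0.212, "0.5-1.0": 0.212, "1.0-1.5": 0.208, "1.5-3.0": 0.175, ">=3.0": 0.063, "missing": 0.130},
    "smoking": {"never": 0.55, "former": 0.25, "current": 0.20},
    "drinking": {"no": 0.50, "yes": 0.50},
}


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant's raw measurements and questionnaire covariates.

    Concentrations are raw assay readings in µg/L.  ``below_lod_*`` flags
    mark readings under the species' limit of detection; the stored value
    remains the underlying truth so the generator stays invertible for
    round-trip checks, and the flag drives LOD/2 substitution downstream.
    """

    subject_id: str
    stratum: str  # "background" | "high_exposure"
    sex: str
    age_group: str
    residence_group: str
    water_source: str
    seafood_last_week: str
    distance_group: str
    smoking: str
    drinking: str
    creatinine: float  # g/L
    as3: float  # µg/L
    as5: float
    mma: float
    dma: float
    has_aas: float  # summed-assay reading, µg/L
    below_lod_as3: bool = False
    below_lod_as5: bool = False
    below_lod_mma: bool = False
    below_lod_dma: bool = False

    def __post_init__(self) -> None:
        if self.creatinine <= 0:
            raise ValueError(f"creatinine must be > 0, got {self.creatinine}")
        for name in ("as3", "as5", "mma", "dma", "has_aas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Default "true" proportion curves for the generator.  AsIII and MMA use
#: the reference shapes; the AsV quadratic is re-parameterized so its vertex
#: sits beyond the realistic concentration range, making the AsV share
#: decrease with the total throughout — the inverse AsV/MMA trend the
#: analysis is designed to detect.  (The reference AsV quadratic turns
#: upward almost immediately and is unusable as a generating truth.)  DMA
#: is generated as the complement; its display curve is the reference one.
DEFAULT_GENERATOR_CURVES = ModelSet(
    as3=ProportionModel("as3", "power", (2.724, 0.529)),
    as5=ProportionModel("as5", "quadratic", (0.00005, -0.035, 7.114)),
    mma=ProportionModel("mma", "quadratic", (0.0000645, -0.0381, 6.773)),
    dma=ProportionModel("dma", "quadratic", (-0.000184, 0.106, 84.716)),
)


@dataclass(frozen=True)
class CohortParams:
    """Generator configuration.

    ``dma_gm``/``dma_gsd`` set the geometric mean and geometric SD of
    creatinine-adjusted DMA, the species that dominates the total; the
    total itself is scaled up from DMA by the model-implied DMA share.
    ``covariate_effects`` maps ``"factor=level"`` keys to additive shifts
    (percentage points) of the inorganic proportion, mirroring covariate
    effects that act on speciation rather than on exposure magnitude.
    """

    n_subjects: int
    seed: int = 0
    dma_gm: float = 70.0
    dma_gsd: float = 2.2
    prop_curves: ModelSet = field(default_factory=lambda: DEFAULT_GENERATOR_CURVES)
    prop_noise_sd: float = 3.0  # percentage points, per minor species
    curve_h_cap: float | None = 300.0  # µg/g-cr; curves evaluated at min(h, cap)
    assay_offset: float = 18.0  # µg/g-cr, speciated sum minus summed assay
    assay_noise_cv: float = 0.1
    creatinine_range: tuple[float, float] = (0.4, 2.5)
    lod: LODConfig = field(default_factory=LODConfig)
    frac_high_stratum: float = 14 / 457
    high_stratum_ias_multiplier: float = 50.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex=male": 3.0}
    )

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.dma_gm <= 0:
            raise ValueError("dma_gm must be > 0")
        if self.dma_gsd <= 1:
            raise ValueError("dma_gsd must be > 1")
        if self.prop_noise_sd < 0:
            raise ValueError("prop_noise_sd must be >= 0")
        if self.assay_noise_cv < 0:
            raise ValueError("assay_noise_cv must be >= 0")
        if self.curve_h_cap is not None and self.curve_h_cap <= 0:
            raise ValueError("curve_h_cap must be > 0 or None")
        if not 0 <= self.frac_high_stratum <= 1:
            raise ValueError("frac_high_stratum must be in [0, 1]")
        if self.high_stratum_ias_multiplier < 1:
            raise ValueError("high_stratum_ias_multiplier must be >= 1")
        lo, hi = self.creatinine_range
        if not (0 < lo < hi):
            raise ValueError("creatinine_range must satisfy 0 < low < high")
        for key in self.covariate_effects:
            if "=" not in key:
                raise ValueError(
                    f"covariate_effects key {key!r} must be 'factor=level'"
                )


def _dma_share_at(
    curves: ModelSet, h: np.ndarray | float, cap: float | None = None
) -> np.ndarray | float:
    """Model-implied DMA share (fraction of 1) at total ``h``.

    With ``cap`` set, curves are evaluated at ``min(h, cap)`` — flat
    extrapolation beyond their trusted range, where quadratic shapes
    otherwise leave the physical proportion range.
    """
    h_eval = np.minimum(h, cap) if cap is not None else h
    minor = 0.0
    for m in curves.minor_species():
        minor = minor + evaluate_proportion_model(m, h_eval).value
    return (100.0 - np.minimum(minor, 100.0)) / 100.0


def _solve_totals_from_dma(
    curves: ModelSet, dma: np.ndarray, cap: float | None = None
) -> np.ndarray:
    """Per-subject total implied by a DMA concentration and the curves.

    Fixed-point iteration on h = dma / share(h); the DMA share is flat
    (0.80–0.95) over realistic totals, so the map is a strong contraction
    and a few dozen vectorized iterations converge far below the tolerance
    that matters downstream.  Solving per subject (rather than once at the
    geometric mean) keeps the noiseless DMA geometric mean exactly at its
    configured value regardless of share curvature across the cohort.
    """
    h = dma / 0.92
    for _ in range(100):
        share = np.maximum(_dma_share_at(curves, h, cap), 1e-6)
        h_new = dma / share
        if np.all(np.abs(h_new - h) < 1e-12 * h):
            return h_new
        h = h_new
    return h


def generate_cohort(params: CohortParams) -> list[SubjectRecord]:
    """Generate a reproducible synthetic cohort.

    The recipe, per subject: draw the true DMA concentration (µg/g-cr)
    log-normally and solve the speciated total from the curve-implied DMA
    share; take minor-species proportions from the configured curves
    plus truncated Gaussian noise; apply covariate shifts to the inorganic
    share; set DMA as the complement; apply the high-exposure inorganic
    multiplier in the rare stratum; derive the summed-assay value as the
    total minus the assay offset with multiplicative noise (floored at 0);
    convert to raw µg/L via sampled creatinine; and flag readings whose
    µg/L value sits below the species LOD.
    """
    params.validate()
    n = params.n_subjects
    rng = np.random.default_rng(params.seed)
    if n == 0:
        return []

    stratum = np.where(
        rng.random(n) < params.frac_high_stratum, "high_exposure", "background"
    )
    covariates = {
        name: rng.choice(list(dist), size=n, p=list(dist.values()))
        for name, dist in COVARIATE_DISTRIBUTIONS.items()
    }
    lo, hi = params.creatinine_range
    creatinine = rng.uniform(lo, hi, size=n)

    dma_true = params.dma_gm * np.exp(rng.normal(0.0, np.log(params.dma_gsd), size=n))
    h = _solve_totals_from_dma(params.prop_curves, dma_true, params.curve_h_cap)
    h_eval = np.minimum(h, params.curve_h_cap) if params.curve_h_cap is not None else h

    # minor-species proportions: curve + noise, truncated to physical range
    props = {}
    for model in params.prop_curves.minor_species():
        p = evaluate_proportion_model(model, h_eval).value
        if params.prop_noise_sd > 0:
            p = p + rng.normal(0.0, params.prop_noise_sd, size=n)
        props[model.species] = np.clip(p, 0.0, 100.0)

    # covariate effects: additive shift of the inorganic share, split
    # evenly between AsIII and AsV
    for key, delta in params.covariate_effects.items():
        factor, level = key.split("=", 1)
        mask = covariates[factor] == level
        props["as3"] = np.clip(props["as3"] + np.where(mask, delta / 2.0, 0.0), 0.0, 100.0)
        props["as5"] = np.clip(props["as5"] + np.where(mask, delta / 2.0, 0.0), 0.0, 100.0)

    minor_sum = props["as3"] + props["as5"] + props["mma"]
    over = minor_sum > 100.0
    if over.any():
        scale = np.where(over, 100.0 / minor_sum, 1.0)
        for sp in ("as3", "as5", "mma"):
            props[sp] = props[sp] * scale
        minor_sum = np.minimum(minor_sum, 100.0)

    # concentrations on the creatinine-adjusted scale; DMA is the exact
    # complement so the four species sum to the drawn total
    c3 = props["as3"] / 100.0 * h
    c5 = props["as5"] / 100.0 * h
    cm = props["mma"] / 100.0 * h
    cd = np.maximum(h - (c3 + c5 + cm), 0.0)  # exact complement; guard -0.0 ulps

    high = stratum == "high_exposure"
    if high.any():
        c3 = np.where(high, c3 * params.high_stratum_ias_multiplier, c3)
        c5 = np.where(high, c5 * params.high_stratum_ias_multiplier, c5)
    h_total = c3 + c5 + cm + cd

    aas = h_total - params.assay_offset
    if params.assay_noise_cv > 0:
        aas = aas * (1.0 + rng.normal(0.0, params.assay_noise_cv, size=n))
    aas = np.maximum(aas, 0.0)

    records: list[SubjectRecord] = []
    lod = params.lod
    for i in range(n):
        ug_l = {
            "as3": c3[i] * creatinine[i],
            "as5": c5[i] * creatinine[i],
            "mma": cm[i] * creatinine[i],
            "dma": cd[i] * creatinine[i],
        }
        records.append(
            SubjectRecord(
                subject_id=f"S{i:05d}",
                stratum=str(stratum[i]),
                sex=str(covariates["sex"][i]),
                age_group=str(covariates["age_group"][i]),
                residence_group=str(covariates["residence_group"][i]),
                water_source=str(covariates["water_source"][i]),
                seafood_last_week=str(covariates["seafood_last_week"][i]),
                distance_group=str(covariates["distance_group"][i]),
                smoking=str(covariates["smoking"][i]),
                drinking=str(covariates["drinking"][i]),
                creatinine=float(creatinine[i]),
                as3=float(ug_l["as3"]),
                as5=float(ug_l["as5"]),
                mma=float(ug_l["mma"]),
                dma=float(ug_l["dma"]),
                has_aas=float(aas[i] * creatinine[i]),
                below_lod_as3=bool(ug_l["as3"] < lod.lod_as3),
                below_lod_as5=bool(ug_l["as5"] < lod.lod_as5),
                below_lod_mma=bool(ug_l["mma"] < lod.lod_mma),
                below_lod_dma=bool(ug_l["dma"] < lod.lod_dma),
            )
        )
    return records


def generate_proportion_observations(
    models: ModelSet,
    h_values: Sequence[float],
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy species-proportion observations at given totals.

    For each ``h`` and each species in ``models`` (DMA included if present),
    the observed proportion is ``curve(h) + N(0, noise_sd)`` truncated to
    [0, 100].  A fixture generator for curve-recovery tests; with
    ``noise_sd=0`` the output is the curves evaluated exactly.
    """
    h_arr = np.asarray(h_values, dtype=float)
    if np.any(h_arr <= 0):
        raise ValueError("h_values must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    model_list = list(models.minor_species())
    if models.dma is not None:
        model_list.append(models.dma)
    for model in model_list:
        clean = evaluate_proportion_model(model, h_arr).value
        if noise_sd > 0:
            obs = np.clip(clean + rng.normal(0.0, noise_sd, size=h_arr.size), 0.0, 100.0)
        else:
            obs = np.asarray(clean, dtype=float)
        for h_i, p_i in zip(h_arr, obs):
            rows.append({"h": float(h_i), "species": model.species, "proportion": float(p_i)})
    return pd.DataFrame(rows)


def cohort_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame with the on-disk CSV schema."""
    cols = {
        "subject_id": [],
        "stratum": [],
        "sex": [],
        "age_group": [],
        "residence_group": [],
        "water_source": [],
        "seafood_last_week": [],
        "distance_group": [],
        "smoking": [],
        "drinking": [],
        "creatinine_g_per_L": [],
        "as3_ug_L": [],
        "as5_ug_L": [],
        "mma_ug_L": [],
        "dma_ug_L": [],
        "has_aas_ug_L": [],
        "below_lod_as3": [],
        "below_lod_as5": [],
        "below_lod_mma": [],
        "below_lod_dma": [],
    }
    rename = {
        "creatinine_g_per_L": "creatinine",
        "as3_ug_L": "as3",
        "as5_ug_L": "as5",
        "mma_ug_L": "mma",
        "dma_ug_L": "dma",
        "has_aas_ug_L": "has_aas",
    }
    for rec in records:
        for col in cols:
            cols[col].append(getattr(rec, rename.get(col, col)))
    return pd.DataFrame(cols)


def write_cohort_csv(records: Sequence[SubjectRecord], path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)
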