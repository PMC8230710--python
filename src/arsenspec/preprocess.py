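"""Raw subject records → analysis-ready creatinine-adjusted speciation profiles.

The preprocessing chain applies the study eligibility filter (urinary
creatinine within the clinical reference range 0.3–3.0 g/L), substitutes
LOD/2 for readings below each species' limit of detection, converts µg/L to
µg/g-creatinine, and computes subtotals and species proportions relative to
the speciated total hAs_ICP (the sum of AsIII + AsV + MMA + DMA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LODConfig",
    "CREATININE_REFERENCE_RANGE",
    "filter_by_creatinine",
    "substitute_lod",
    "creatinine_adjust",
    "build_profiles",
    "assign_quartiles",
    "read_cohort_csv",
    "write_profiles_csv",
    "read_profiles_csv",
]

#: clinical reference range for urinary creatinine (g/L), bounds inclusive
CREATININE_REFERENCE_RANGE = (0.3, 3.0)

#: covariate columns carried from the cohort through to profiles
COVARIATE_COLUMNS = (
    "stratum",
    "sex",
    "age_group",
    "residence_group",
    "water_source",
    "seafood_last_week",
    "distance_group",
    "smoking",
    "drinking",
)

PROPORTION_COLUMNS = (
    "prop_as3",
    "prop_as5",
    "prop_ias",
    "prop_mma",
    "prop_dma",
    "prop_oas",
    "prop_non_dma",
)


@dataclass(frozen=True)
class LODConfig:
    """Per-species limits of detection, in the unit of the raw readings (µg/L)."""

    lod_as3: float = 0.100
    lod_as5: float = 0.164
    lod_mma: float = 0.078
    lod_dma: float = 0.022

    def __post_init__(self) -> None:
        for name in ("lod_as3", "lod_as5", "lod_mma", "lod_dma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def for_species(self, species: str) -> float:
        return getattr(self, f"lod_{species}")


def filter_by_creatinine(
    records: Sequence["SubjectRecord"],
    low: float = CREATININE_REFERENCE_RANGE[0],
    high: float = CREATININE_REFERENCE_RANGE[1],
) -> tuple[list["SubjectRecord"], int]:
    """Keep subjects whose creatinine lies in ``[low, high]`` (inclusive).

    Records with non-positive creatinine are rejected (and logged) rather
    than raising: such values are physically impossible readings.  Returns
    the kept records in input order and the count excluded.
    """
    if not low < high:
        raise ValueError("creatinine filter requires low < high")
    kept: list["SubjectRecord"] = []
    excluded = 0
    for rec in records:
        if rec.creatinine <= 0:
            logger.warning(
                "subject %s rejected: non-positive creatinine %.3f g/L",
                rec.subject_id,
                rec.creatinine,
            )
            excluded += 1
            continue
        if low <= rec.creatinine <= high:
            kept.append(rec)
        else:
            excluded += 1
    return kept, excluded


def substitute_lod(value: float, censored: bool, lod: float | None) -> float:
    """LOD/2 substitution for a single reading.

    Uncensored values pass through unchanged; censored values are replaced
    by half the limit of detection.  Idempotent on already-substituted data.
    """
    if not censored:
        return value
    if lod is None:
        raise ValueError("censored reading requires a limit of detection")
    if lod <= 0:
        raise ValueError("limit of detection must be > 0")
    return lod / 2.0


def creatinine_adjust(conc, creatinine):
    """Convert µg/L to µg/g-creatinine: ``conc / creatinine`` (creatinine in g/L)."""
    creatinine = np.asarray(creatinine, dtype=float)
    if np.any(creatinine <= 0):
        raise ValueError("creatinine must be > 0 for adjustment")
    return np.asarray(conc, dtype=float) / creatinine


def build_profiles(
    records: Iterable["SubjectRecord"],
    lod: LODConfig | None = None,
) -> pd.DataFrame:
    """Build speciation profiles (one row per subject) from filtered records.

    Applies LOD/2 substitution then creatinine adjustment per species, and
    derives subtotals (inorganic = AsIII+AsV, organic = MMA+DMA), the
    speciated total ``has_icp``, the creatinine-adjusted summed-assay value
    ``has_aas_cr``, and proportions (%) of each species relative to
    ``has_icp``.  Subjects with a zero speciated total (possible only with
    degenerate inputs, since LOD/2 substitution is strictly positive) are
    dropped from the output with a logged warning.
    """
    lod = lod or LODConfig()
    rows = []
    for rec in records:
        row: dict = {"subject_id": rec.subject_id}
        for col in COVARIATE_COLUMNS:
            row[col] = getattr(rec, col)
        cr = rec.creatinine
        row["creatinine"] = cr
        for sp in ("as3", "as5", "mma", "dma"):
            raw = getattr(rec, sp)
            censored = getattr(rec, f"below_lod_{sp}")
            sub = substitute_lod(raw, censored, lod.for_species(sp))
            row[f"{sp}_cr"] = float(creatinine_adjust(sub, cr))
            row[f"censored_{sp}"] = bool(censored)
        row["has_aas_cr"] = float(creatinine_adjust(rec.has_aas, cr))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["ias_subtotal"] = df["as3_cr"] + df["as5_cr"]
    df["oas_subtotal"] = df["mma_cr"] + df["dma_cr"]
    df["has_icp"] = df["ias_subtotal"] + df["oas_subtotal"]
    zero_total = df["has_icp"] <= 0
    if zero_total.any():
        for sid in df.loc[zero_total, "subject_id"]:
            logger.warning(
                "subject %s excluded: zero speciated total, proportions undefined", sid
            )
        df = df.loc[~zero_total].reset_index(drop=True)
    for sp in ("as3", "as5", "mma", "dma"):
        df[f"prop_{sp}"] = 100.0 * df[f"{sp}_cr"] / df["has_icp"]
    df["prop_ias"] = df["prop_as3"] + df["prop_as5"]
    df["prop_oas"] = df["prop_mma"] + df["prop_dma"]
    df["prop_non_dma"] = df["prop_as3"] + df["prop_as5"] + df["prop_mma"]
    df["quartile"] = pd.Series([""] * len(df), dtype=object)
    return df


def assign_quartiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Label subjects Q1–Q4 by the empirical quartiles of ``has_icp``.

    Cut points are the 25/50/75th percentiles (linear interpolation); a
    value equal to a cut point goes to the lower quartile.  With heavily
    tied data the quartiles degenerate (everything equal → all Q1, logged).
    """
    if len(profiles) < 4:
        raise ValueError("quartile assignment requires at least 4 profiles")
    h = profiles["has_icp"].to_numpy(dtype=float)
    q1, q2, q3 = np.percentile(h, [25, 50, 75])
    labels = np.where(h <= q1, "Q1", np.where(h <= q2, "Q2", np.where(h <= q3, "Q3", "Q4")))
    if len(np.unique(labels)) == 1:
        logger.warning("degenerate quartiles: all has_icp values identical")
    out = profiles.copy()
    out["quartile"] = labels
    return out


# ---------------------------------------------------------------------------
# I/O — cohort CSV (written by the synthetic module) and profiles CSV


def read_cohort_csv(path) -> list["SubjectRecord"]:
    """Read a cohort CSV (schema of :func:`arsenspec.synthetic.write_cohort_csv`)."""
    from .synthetic import SubjectRecord  # deferred: avoid import cycle

    df = pd.read_csv(path, dtype={"subject_id": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=row.subject_id,
                stratum=row.stratum,
                sex=row.sex,
                age_group=row.age_group,
                residence_group=row.residence_group,
                water_source=row.water_source,
                seafood_last_week=row.seafood_last_week,
                distance_group=row.distance_group,
                smoking=row.smoking,
                drinking=row.drinking,
                creatinine=float(row.creatinine_g_per_L),
                as3=float(row.as3_ug_L),
                as5=float(row.as5_ug_L),
                mma=float(row.mma_ug_L),
                dma=float(row.dma_ug_L),
                has_aas=float(row.has_aas_ug_L),
                below_lod_as3=bool(row.below_lod_as3),
                below_lod_as5=bool(row.below_lod_as5),
                below_lod_mma=bool(row.below_lod_mma),
                below_lod_dma=bool(row.below_lod_dma),
            )
        )
    return records


def write_profiles_csv(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)


def read_profiles_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "quartile" in df.columns:
        df["quartile"] = df["quartile"].fillna("").astype(str)
    return df
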