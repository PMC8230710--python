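"""Interchangeability projection: species estimates from the summed assay.

Given a subject's summed hazardous-arsenic reading (µg/g-cr) and fitted
proportion-versus-total curves for AsIII, AsV and MMA, each minor species
is estimated as its predicted share of the total, and DMA is taken as the
remainder so the four estimates conserve the input total exactly (mass
balance).  Validation regresses the observed species concentration on the
estimate, per species, in the orientation observed = slope·estimated +
intercept; on realistic cohorts DMA projects well (it carries most of the
total) while the minor species do not — quantifying how much speciation
information a summed assay genuinely contains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import additive_bias_correction, ols_fit
from .curves import ModelSet, evaluate_proportion_model

__all__ = ["ProjectionResult", "project_species", "assess_projection_fit", "run_interchangeability"]

_SPECIES = ("as3", "as5", "mma", "dma")


@dataclass(frozen=True)
class ProjectionResult:
    """Per-subject species estimates plus per-species validation fits.

    ``estimates`` columns: subject_id, h_input, est_as3..est_dma,
    clamped_minor, rescaled_dma flags.  ``fits`` maps species →
    {slope, intercept, r2} of observed on estimated.  ``shift`` is the
    additive assay correction applied to the summed reading (0 when
    uncorrected); ``n_excluded`` counts subjects with a non-positive
    summed reading, which cannot be projected.
    """

    estimates: pd.DataFrame
    fits: dict[str, dict[str, float]]
    shift: float
    n_excluded: int


def project_species(
    h: float, models: ModelSet, clamp: bool = True
) -> tuple[float, float, float, float, dict[str, bool]]:
    """Estimate the four species (µg/g-cr) from one summed reading ``h``.

    The three modelled species take their curve-predicted share of ``h``;
    DMA is the remainder.  With ``clamp`` set, negative curve predictions
    are floored at zero, and if the three minor estimates overshoot ``h``
    (negative remainder) they are rescaled proportionally so the estimates
    still sum to ``h`` exactly.
    """
    if h <= 0:
        raise ValueError("summed reading must be > 0 to project")
    flags = {"clamped_minor": False, "rescaled_dma": False}
    est = {}
    for model in models.minor_species():
        evaluated = evaluate_proportion_model(model, h)
        raw_share = evaluated.raw
        if clamp and raw_share < 0.0:
            flags["clamped_minor"] = True
            raw_share = 0.0
        est[model.species] = raw_share / 100.0 * h
    minor_sum = est["as3"] + est["as5"] + est["mma"]
    dma = h - minor_sum
    if dma < 0.0:
        flags["rescaled_dma"] = True
        scale = h / minor_sum if minor_sum > 0 else 0.0
        for sp in ("as3", "as5", "mma"):
            est[sp] *= scale
        dma = h - (est["as3"] + est["as5"] + est["mma"])
        dma = max(dma, 0.0)
    return est["as3"], est["as5"], est["mma"], dma, flags


def assess_projection_fit(
    observed: dict[str, np.ndarray], estimated: dict[str, np.ndarray]
) -> dict[str, dict[str, float]]:
    """Per-species OLS of observed on estimated: slope, intercept, R²."""
    fits = {}
    for sp in observed:
        slope, intercept, r2 = ols_fit(estimated[sp], observed[sp])
        fits[sp] = {"slope": slope, "intercept": intercept, "r2": r2}
    return fits


def run_interchangeability(
    profiles: pd.DataFrame,
    models: ModelSet,
    use_corrected_aas: bool = False,
    clamp: bool = True,
) -> ProjectionResult:
    """Project every subject's species from the summed assay and validate.

    With ``use_corrected_aas`` the additive inter-assay shift (the OLS
    intercept of the speciated sum on the summed assay, estimated from
    these profiles) is added to the summed reading before projection.
    Subjects whose (possibly corrected) reading is non-positive cannot be
    projected and are excluded from estimates and fits.
    """
    h_in = profiles["has_aas_cr"].to_numpy(dtype=float)
    shift = 0.0
    if use_corrected_aas:
        shift, h_in = additive_bias_correction(h_in, profiles["has_icp"].to_numpy(dtype=float))
    ok = h_in > 0
    n_excluded = int((~ok).sum())
    rows = []
    for sid, h in zip(profiles.loc[ok, "subject_id"], h_in[ok]):
        e3, e5, em, ed, flags = project_species(float(h), models, clamp=clamp)
        rows.append(
            {
                "subject_id": sid,
                "h_input": float(h),
                "est_as3": e3,
                "est_as5": e5,
                "est_mma": em,
                "est_dma": ed,
                **flags,
            }
        )
    estimates = pd.DataFrame(rows)
    observed = {sp: profiles.loc[ok, f"{sp}_cr"].to_numpy(dtype=float) for sp in _SPECIES}
    est_arr = {sp: estimates[f"est_{sp}"].to_numpy(dtype=float) for sp in _SPECIES}
    fits = assess_projection_fit(observed, est_arr)
    return ProjectionResult(estimates=estimates, fits=fits, shift=float(shift), n_excluded=n_excluded)
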