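"""Concentration-dependent species-proportion curves.

Urinary arsenic speciation in exposed populations is dominated by DMA
(dimethylarsenic acid), with the shares of arsenite (AsIII), arsenate (AsV)
and monomethylarsinic acid (MMA) varying systematically with the total
hazardous-arsenic concentration (hAs, µg/g-creatinine).  Each minor species
is described by a simple parametric curve of proportion (%) versus total:

* ``power``      — ``p(h) = a · h^(-b)``, suited to shares that decay from a
  pole at low totals (AsIII);
* ``quadratic``  — ``p(h) = c2·h² + c1·h + c0``, suited to shallow U- or
  hump-shaped trends (AsV, MMA, DMA).

DMA is usually treated as the complement of the modelled species, so a
:class:`ModelSet` needs only the three minor species; a DMA curve may be
attached for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np

__all__ = [
    "ProportionModel",
    "ModelSet",
    "EvaluatedProportion",
    "evaluate_proportion_model",
    "REFERENCE_PROPORTION_CURVES",
    "DEFAULT_PROPORTION_CURVES",
    "SPECIES",
]

#: canonical species keys used throughout the package
SPECIES = ("as3", "as5", "mma", "dma")

Form = Literal["power", "quadratic"]


@dataclass(frozen=True)
class ProportionModel:
    """A fitted (or assumed) proportion-versus-total curve for one species.

    Parameters
    ----------
    species:
        One of ``"as3"``, ``"as5"``, ``"mma"``, ``"dma"``.
    form:
        ``"power"`` with coefficients ``(a, b)`` meaning ``a·h^(-b)``, or
        ``"quadratic"`` with coefficients ``(c2, c1, c0)`` meaning
        ``c2·h² + c1·h + c0``.
    coefficients:
        Curve coefficients in the order given above.
    r2, adj_r2:
        Goodness of fit on the data the curve was fitted to (``None`` for
        assumed curves).
    fit_domain:
        ``(h_min, h_max)`` in µg/g-cr over which the curve was fitted.
    """

    species: str
    form: Form
    coefficients: tuple[float, ...]
    r2: float | None = None
    adj_r2: float | None = None
    fit_domain: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        n_expected = {"power": 2, "quadratic": 3}
        if self.form not in n_expected:
            raise ValueError(f"unknown model form {self.form!r}")
        if len(self.coefficients) != n_expected[self.form]:
            raise ValueError(
                f"{self.form} form requires {n_expected[self.form]} "
                f"coefficients, got {len(self.coefficients)}"
            )
        if self.r2 is not None and self.adj_r2 is not None:
            if self.adj_r2 > self.r2 + 1e-12:
                raise ValueError("adj_r2 cannot exceed r2")


class EvaluatedProportion(NamedTuple):
    """Curve evaluation: ``value`` is clamped to [0, 100], ``raw`` is not."""

    value: np.ndarray | float
    raw: np.ndarray | float


def evaluate_proportion_model(
    model: ProportionModel, h: "np.typing.ArrayLike"
) -> EvaluatedProportion:
    """Evaluate a proportion curve at total concentration ``h`` (µg/g-cr).

    Returns both the physically clamped value (in [0, 100] %) and the raw
    curve value; quadratics can stray outside the physical range far from
    their fit domain.  The power form requires ``h > 0``.
    """
    h_arr = np.asarray(h, dtype=float)
    scalar = h_arr.ndim == 0
    h_arr = np.atleast_1d(h_arr)
    if model.form == "power":
        if np.any(h_arr <= 0):
            raise ValueError("power-form curves require h > 0")
        a, b = model.coefficients
        raw = a * h_arr ** (-b)
    else:
        c2, c1, c0 = model.coefficients
        raw = c2 * h_arr**2 + c1 * h_arr + c0
    value = np.clip(raw, 0.0, 100.0)
    if scalar:
        return EvaluatedProportion(float(value[0]), float(raw[0]))
    return EvaluatedProportion(value, raw)


@dataclass(frozen=True)
class ModelSet:
    """Proportion curves for the three minor species, plus optional DMA.

    Projection of species from a summed assay uses only AsIII, AsV and MMA;
    DMA is derived by difference so that the four estimates conserve the
    measured total.  The optional DMA member is for display/diagnostics.
    """

    as3: ProportionModel
    as5: ProportionModel
    mma: ProportionModel
    dma: ProportionModel | None = None

    def __post_init__(self) -> None:
        for name in ("as3", "as5", "mma"):
            m = getattr(self, name)
            if m.species != name:
                raise ValueError(f"model under key {name!r} is for {m.species!r}")
        if self.dma is not None and self.dma.species != "dma":
            raise ValueError("dma slot holds a non-DMA model")

    def minor_species(self) -> tuple[ProportionModel, ProportionModel, ProportionModel]:
        return (self.as3, self.as5, self.mma)

    def to_dict(self) -> dict:
        out = {}
        for name in SPECIES:
            m = getattr(self, name, None)
            if m is None:
                continue
            out[name] = {
                "form": m.form,
                "coefficients": list(m.coefficients),
                "r2": m.r2,
                "adj_r2": m.adj_r2,
                "fit_domain": list(m.fit_domain) if m.fit_domain else None,
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSet":
        models = {}
        for name, spec_d in d.items():
            models[name] = ProportionModel(
                species=name,
                form=spec_d["form"],
                coefficients=tuple(spec_d["coefficients"]),
                r2=spec_d.get("r2"),
                adj_r2=spec_d.get("adj_r2"),
                fit_domain=tuple(spec_d["fit_domain"]) if spec_d.get("fit_domain") else None,
            )
        return cls(**models)


#: Reference curve set for a DMA-dominated mine-area cohort: a power-law
#: decay for AsIII and shallow quadratics for AsV, MMA and DMA.  These are
#: the shapes a percentile-section fit typically returns on such cohorts;
#: note the AsV and DMA quadratics are only meaningful inside a bounded
#: concentration range — extrapolated far beyond it the positive curvature
#: of the AsV term takes over and the shares leave the physical range.
REFERENCE_PROPORTION_CURVES = ModelSet(
    as3=ProportionModel("as3", "power", (2.724, 0.529)),
    as5=ProportionModel("as5", "quadratic", (0.0000998, -0.000603, 7.114)),
    mma=ProportionModel("mma", "quadratic", (0.0000645, -0.0381, 6.773)),
    dma=ProportionModel("dma", "quadratic", (-0.000184, 0.106, 84.716)),
)

#: backwards-compatible alias
DEFAULT_PROPORTION_CURVES = REFERENCE_PROPORTION_CURVES
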