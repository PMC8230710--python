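"""Stratified distribution summaries for urinary biomarkers.

Exposure biomarkers are approximately log-normal, so the summary reports
both arithmetic moments and the geometric mean with a log-scale t-interval,
alongside the median, range and upper percentiles that biomonitoring tables
conventionally print.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["DescriptiveSummary", "summarize_distribution", "stratified_summary_table"]

#: quantities summarized per stratum, in table order
SUMMARY_QUANTITIES = (
    "as3_cr",
    "as5_cr",
    "ias_subtotal",
    "mma_cr",
    "dma_cr",
    "oas_subtotal",
    "has_icp",
    "has_aas_cr",
    "prop_as3",
    "prop_as5",
    "prop_ias",
    "prop_mma",
    "prop_dma",
    "prop_oas",
    "prop_non_dma",
)


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    am: float
    sd: float
    gm: float
    gm_ci: tuple[float, float]
    median: float
    range: tuple[float, float]
    p75: float
    p90: float
    p95: float
    p99: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "am": self.am,
            "sd": self.sd,
            "gm": self.gm,
            "gm_ci_low": self.gm_ci[0],
            "gm_ci_high": self.gm_ci[1],
            "median": self.median,
            "min": self.range[0],
            "max": self.range[1],
            "p75": self.p75,
            "p90": self.p90,
            "p95": self.p95,
            "p99": self.p99,
        }


def summarize_distribution(values, ci_level: float = 0.95) -> DescriptiveSummary:
    """Summarize a positive-valued sample.

    GM = exp(mean(log x)); its CI is the t-interval on the log scale,
    ``exp(mean ± t_{1-α/2, n-1}·sd/√n)``.  SD is the sample SD (n−1
    denominator); percentiles use linear interpolation.  Positivity is
    required for the geometric mean — LOD/2 substitution upstream
    guarantees it for censored readings.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(x <= 0):
        bad = int(np.flatnonzero(x <= 0)[0])
        raise ValueError(f"non-positive value at position {bad}: {x[bad]}")
    n = x.size
    logs = np.log(x)
    log_mean = logs.mean()
    log_sd = logs.std(ddof=1)
    t_mult = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    half = t_mult * log_sd / np.sqrt(n)
    p75, p90, p95, p99 = np.percentile(x, [75, 90, 95, 99])
    return DescriptiveSummary(
        n=n,
        am=float(x.mean()),
        sd=float(x.std(ddof=1)),
        gm=float(np.exp(log_mean)),
        gm_ci=(float(np.exp(log_mean - half)), float(np.exp(log_mean + half))),
        median=float(np.median(x)),
        range=(float(x.min()), float(x.max())),
        p75=float(p75),
        p90=float(p90),
        p95=float(p95),
        p99=float(p99),
    )


def stratified_summary_table(
    profiles: pd.DataFrame,
    strata: str | None = "stratum",
    quantities: tuple[str, ...] = SUMMARY_QUANTITIES,
) -> pd.DataFrame:
    """One DescriptiveSummary row per (stratum × quantity).

    ``strata=None`` summarizes the whole cohort as a single stratum
    ``"all"``.  Raises on an empty stratum (cannot happen with pandas
    groupby on observed data, but guards degenerate categorical input).

    Non-positive values — possible only for the summed-assay reading,
    which is floored at zero when a low total falls under the inter-assay
    offset — are dropped from that quantity's row with a logged note,
    since the geometric mean is undefined for them; ``n`` reflects the
    values actually summarized.
    """
    if strata is None:
        groups = [("all", profiles)]
    else:
        groups = list(profiles.groupby(strata, observed=True))
    if not groups:
        raise ValueError("no strata present in profiles")
    rows = []
    for name, grp in groups:
        if grp.empty:
            raise ValueError(f"empty stratum {name!r}")
        for qty in quantities:
            vals = grp[qty].to_numpy(dtype=float)
            n_nonpos = int((vals <= 0).sum())
            if n_nonpos:
                logger.warning(
                    "stratum %s, quantity %s: dropping %d non-positive values",
                    name,
                    qty,
                    n_nonpos,
                )
                vals = vals[vals > 0]
            summ = summarize_distribution(vals)
            row = {"stratum": name, "quantity": qty}
            row.update(summ.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
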