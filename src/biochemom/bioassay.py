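"""Dose-response fitting and IC50 summarization.

Cell-viability plate data (MTT-style, % viability vs extract concentration)
is fit with a four-parameter logistic (4PL):

    y(x) = lower + (upper - lower) / (1 + (x / inflection)^slope)

With slope > 0 the curve decreases from ``upper`` toward ``lower`` as dose
grows; zero-dose wells anchor the upper asymptote (the power term is only
evaluated for x > 0, where y(0) == upper is the slope>0 limit).  IC50 is the
dose at which the *fitted* curve crosses 50% viability — an absolute-50%
definition, not the curve midpoint — and is only reported when 50% lies
strictly between the fitted asymptotes.  IC50 is natural-log transformed
for all downstream modeling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseFit",
    "BioactivitySummary",
    "fit_4pl",
    "ic50_from_params",
    "summarize_bioactivity",
    "bioassay_to_summaries",
]

#: The assay's dose grid in µg/ml.
DEFAULT_DOSES = (0.0, 25.0, 50.0, 100.0, 200.0)


@dataclass
class DoseResponseFit:
    lower: float            # % viability asymptote at high dose
    upper: float            # % viability asymptote at zero dose
    slope: float            # Hill coefficient, unitless
    inflection: float       # µg/ml, curve midpoint
    ic50: float | None      # µg/ml; None when no 50% crossing exists
    converged: bool
    residual_sse: float
    message: str = ""


@dataclass
class BioactivitySummary:
    """Per-sample IC50 aggregated over plating replicates, with ln IC50."""

    sample_id: str
    ic50_mean: float        # µg/ml
    ic50_sd: float          # µg/ml, n-1 denominator (0 for a single replicate)
    log_ic50: float         # ln(ic50_mean)
    n_replicates: int = 1
    usable: bool = True


def _predict_4pl(params: np.ndarray, doses: np.ndarray) -> np.ndarray:
    lower, upper, slope, inflection = params
    out = np.full_like(doses, upper, dtype=float)
    pos = doses > 0
    out[pos] = lower + (upper - lower) / (1.0 + (doses[pos] / inflection) ** slope)
    return out


def ic50_from_params(lower: float, upper: float, slope: float, inflection: float) -> float | None:
    """Dose where the fitted curve crosses 50% viability, or None.

    Requires 50 strictly between the asymptotes; solves
    (x/c)^b = (upper - 50)/(50 - lower).
    """
    lo, hi = min(lower, upper), max(lower, upper)
    if not (lo < 50.0 < hi):
        return None
    ratio = (upper - 50.0) / (50.0 - lower)
    if ratio <= 0 or slope == 0:
        return None
    return float(inflection * ratio ** (1.0 / slope))


def fit_4pl(
    doses,
    viability,
    slope_starts=(0.5, 1.0, 2.0, 4.0),
    max_nfev: int = 2000,
) -> DoseResponseFit:
    """Multi-start nonlinear least-squares 4PL fit.

    Starts vary the Hill slope; the inflection starts at the geometric mean
    of the positive doses and asymptotes at the observed viability extremes.
    Raises ``ValueError`` for < 4 distinct dose levels; optimizer failure is
    reported via ``converged=False`` rather than an exception.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(viability, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and viability must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("doses and viability must be finite")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct dose levels to fit a 4PL")
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive dose")

    c0 = float(np.exp(np.mean(np.log(pos))))
    lo0, hi0 = float(np.min(y)), float(np.max(y))
    if hi0 - lo0 < 1e-9:  # flat response: asymptotes collapse
        hi0 = lo0 + 1e-6

    def residuals(p):
        return _predict_4pl(p, x) - y

    best = None
    for b0 in slope_starts:
        try:
            sol = least_squares(
                residuals,
                x0=np.array([lo0, hi0, b0, c0]),
                bounds=([-np.inf, -np.inf, 1e-6, 1e-9], [np.inf, np.inf, 50.0, np.inf]),
                max_nfev=max_nfev,
            )
        except Exception as exc:  # pragma: no cover - scipy failure path
            logger.debug("4PL start slope=%s failed: %s", b0, exc)
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol

    if best is None:
        return DoseResponseFit(
            lower=math.nan, upper=math.nan, slope=math.nan, inflection=math.nan,
            ic50=None, converged=False, residual_sse=math.inf,
            message="no optimizer start converged",
        )

    lower, upper, slope, inflection = best.x
    ic50 = ic50_from_params(lower, upper, slope, inflection)
    msg = "" if ic50 is not None else "fitted curve never crosses 50% viability"
    return DoseResponseFit(
        lower=float(lower), upper=float(upper), slope=float(slope),
        inflection=float(inflection), ic50=ic50, converged=True,
        residual_sse=float(2.0 * best.cost), message=msg,
    )


def summarize_bioactivity(per_replicate_ic50, sample_id: str) -> BioactivitySummary:
    """Mean and sample SD across replicate IC50s, plus ln of the mean.

    Undefined (None/NaN) replicates are dropped; if none remain the summary
    is flagged unusable for downstream modeling.
    """
    vals = np.array(
        [v for v in per_replicate_ic50 if v is not None and np.isfinite(v)], dtype=float
    )
    if vals.size == 0:
        logger.warning("sample %s: no usable IC50 replicate; excluded", sample_id)
        return BioactivitySummary(sample_id, math.nan, math.nan, math.nan, 0, usable=False)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return BioactivitySummary(
        sample_id=sample_id,
        ic50_mean=mean,
        ic50_sd=sd,
        log_ic50=float(np.log(mean)),
        n_replicates=int(vals.size),
    )


def bioassay_to_summaries(
    assay: pd.DataFrame, per_plate: bool = True
) -> list[BioactivitySummary]:
    """Fit 4PLs on raw plate data and aggregate to per-sample summaries.

    ``per_plate=True`` (default) fits one curve per plating replicate and
    averages the replicate IC50s; ``False`` pools all wells into one fit.
    """
    out = []
    for sample_id, sub in assay.groupby("sample_id", sort=True):
        ic50s: list[float | None] = []
        if per_plate:
            for _, plate in sub.groupby("plate_rep", sort=True):
                fit = fit_4pl(plate["dose_ug_ml"], plate["viability_pct"])
                ic50s.append(fit.ic50 if fit.converged else None)
        else:
            fit = fit_4pl(sub["dose_ug_ml"], sub["viability_pct"])
            ic50s.append(fit.ic50 if fit.converged else None)
        out.append(summarize_bioactivity(ic50s, str(sample_id)))
    return out
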