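"""Matrix preprocessing: zero handling, transforms, scaling, normality, PCA.

The working transform for modeling is Hellinger (square root of the
within-sample relative abundance) followed by auto-scaling fitted on the
training samples only.  Log transform and Pareto scaling are provided as
comparison candidates and ranked by per-feature Shapiro-Wilk W.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ScalerState",
    "NormalityReport",
    "replace_zeros",
    "drop_zero_variance",
    "hellinger",
    "hellinger_table",
    "log_transform",
    "fit_scaler",
    "apply_scaler",
    "inverse_scaler",
    "normality_screen",
    "pca",
]

DEFAULT_EPSILON = 0.001  # raw-area units used for zero replacement


@dataclass
class ScalerState:
    """Train-fitted centering/scaling so test data never leaks into the fit."""

    mean: np.ndarray      # per-feature mean, transformed-area units
    scale: np.ndarray     # divisor: sd (auto), sqrt(sd) (pareto), 1 (none)
    method: str           # "auto" | "pareto" | "none"


@dataclass
class NormalityReport:
    """Per-feature Shapiro-Wilk results for one transform candidate."""

    transform: str
    w: np.ndarray         # per-feature W in (0, 1]; NaN where skipped
    p: np.ndarray
    median_w: float


def replace_zeros(table: FeatureTable, epsilon: float = DEFAULT_EPSILON) -> FeatureTable:
    """Replace exact-zero peak areas (missing measurements) with ``epsilon``."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    areas = table.areas
    nonzero = areas[areas > 0]
    if nonzero.size and epsilon >= nonzero.min():
        logger.warning(
            "epsilon %g is not small relative to the smallest nonzero area %g",
            epsilon, nonzero.min(),
        )
    return replace(table, areas=np.where(areas == 0.0, epsilon, areas))


def drop_zero_variance(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    """Remove features constant across all samples; keeps survivor order."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples to assess variance")
    constant = np.ptp(table.areas, axis=0) == 0.0
    removed = [f for f, c in zip(table.feature_ids, constant) if c]
    return table.subset_features(np.flatnonzero(~constant)), removed


def hellinger(matrix: np.ndarray, sample_ids: list[str] | None = None) -> np.ndarray:
    """sqrt of within-sample relative abundance; rows land on the unit sphere."""
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("Hellinger transform requires nonnegative areas")
    sums = X.sum(axis=1)
    if np.any(sums <= 0):
        i = int(np.argmax(sums <= 0))
        name = sample_ids[i] if sample_ids else f"row {i}"
        raise ValueError(f"sample {name} has zero total area")
    return np.sqrt(X / sums[:, None])


def hellinger_table(table: FeatureTable) -> FeatureTable:
    return replace(table, areas=hellinger(table.areas, table.sample_ids))


def log_transform(matrix: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Natural log of (area + epsilon); the comparison candidate to Hellinger."""
    return np.log(np.asarray(matrix, dtype=float) + epsilon)


def fit_scaler(train_matrix: np.ndarray, method: str = "auto") -> ScalerState:
    X = np.asarray(train_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples to fit a scaler")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if method in ("auto", "pareto") and np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(f"zero training standard deviation at feature index {j}")
    if method == "auto":
        scale = sd
    elif method == "pareto":
        scale = np.sqrt(sd)
    elif method == "none":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return ScalerState(mean=mean, scale=scale, method=method)


def apply_scaler(matrix: np.ndarray, state: ScalerState) -> np.ndarray:
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != state.mean.shape[0]:
        raise ValueError("matrix width does not match scaler state")
    return (X - state.mean) / state.scale


def inverse_scaler(scaled: np.ndarray, state: ScalerState) -> np.ndarray:
    return np.asarray(scaled, dtype=float) * state.scale + state.mean


_TRANSFORMS = ("hellinger+auto", "log+auto", "hellinger+pareto", "log+pareto")


def normality_screen(
    matrix: np.ndarray,
    candidates: tuple[str, ...] = _TRANSFORMS,
    epsilon: float = DEFAULT_EPSILON,
) -> list[NormalityReport]:
    """Shapiro-Wilk W per feature under each candidate transform+scaling.

    Candidates are ranked by median W (descending); features with fewer than
    3 samples or a constant vector are skipped with a warning.  This mirrors
    the practice of choosing the transform that leaves per-feature
    distributions closest to normal before regression modeling.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    reports = []
    for name in candidates:
        tname, sname = name.split("+")
        T = hellinger(X) if tname == "hellinger" else log_transform(X, epsilon)
        sd = T.std(axis=0, ddof=1)
        keep = sd > 0
        S = np.full_like(T, np.nan)
        if np.any(keep):
            state = ScalerState(
                mean=T.mean(axis=0),
                scale=np.where(keep, sd if sname == "auto" else np.sqrt(sd), 1.0),
                method=sname,
            )
            S = apply_scaler(T, state)
        w = np.full(X.shape[1], np.nan)
        p = np.full(X.shape[1], np.nan)
        for j in range(X.shape[1]):
            col = S[:, j]
            if n < 3 or not keep[j] or np.ptp(col) == 0:
                logger.warning("feature %d skipped in normality screen (%s)", j, name)
                continue
            res = stats.shapiro(col)
            w[j], p[j] = res.statistic, res.pvalue
        median_w = float(np.nanmedian(w)) if np.any(np.isfinite(w)) else np.nan
        reports.append(NormalityReport(transform=name, w=w, p=p, median_w=median_w))
    reports.sort(key=lambda r: -(r.median_w if np.isfinite(r.median_w) else -np.inf))
    return reports


def normality_report_frame(reports: list[NormalityReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {"transform": [r.transform for r in reports],
         "median_w": [r.median_w for r in reports]}
    )


def pca(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based principal component analysis.

    Input is centered internally.  Returns ``(scores, loadings,
    explained_fraction)`` with components ordered by decreasing variance;
    the explained fractions sum to 1 over all returned components.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return scores, Vt.T, frac
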