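"""Feature importance on the final PLS model: VIP, Selectivity Ratio,
direction of effect, and candidate selection.

VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja/||w_a||)^2 ] / sum_a SSY_a ),
with SSY_a = q_a^2 (t_a' t_a), so the mean squared VIP over features is 1
and the conventional influence cut is VIP > 1.

The Selectivity Ratio projects the scaled training matrix onto the
normalized regression vector ("target projection"): t_TP = X b / ||b||,
p_TP = X' t_TP / (t_TP' t_TP); per feature, SR_j is the ratio of variance
explained by the rank-one reconstruction t_TP p_TP_j to the residual
variance.  Features proportional to the target-projection score have
unbounded SR; those are capped and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bioassay import BioactivitySummary
from .core_io import Candidate, CandidateReport, FeatureTable
from .models import PlsModel

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionScores",
    "vip_scores",
    "selectivity_ratio",
    "assign_direction",
    "select_candidates",
]

SR_CAP = 1e6  # reported SR for zero-residual ("perfect") features


@dataclass
class SelectionScores:
    feature_ids: list[str]
    vip: np.ndarray
    sr: np.ndarray
    vip_threshold: float
    sr_threshold: float
    direction: dict[str, str]                 # feature_id -> positive/negative_activity
    sr_capped: list[str]                      # features with zero SR residual
    top_means: dict[str, float] | None = None  # mean raw area in most-active group
    bottom_means: dict[str, float] | None = None

    @property
    def passes_vip(self) -> np.ndarray:
        return self.vip > self.vip_threshold

    @property
    def passes_sr(self) -> np.ndarray:
        return self.sr > self.sr_threshold


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable Importance in Projection for a fitted PLS1 model."""
    W, T, q = model.weights, model.x_scores, model.y_loadings
    if W.shape[1] < 1:
        raise ValueError("model has no components")
    p = W.shape[0]
    ssy = q ** 2 * np.einsum("na,na->a", T, T)       # y-variance per component
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no y-variance; VIP undefined")
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ssy) / total)


def selectivity_ratio(model: PlsModel, X_scaled: np.ndarray,
                      cap: float = SR_CAP) -> tuple[np.ndarray, list[int]]:
    """Per-feature SR on the matrix the model was fit to.

    Returns (sr, capped_indices); ``capped_indices`` lists features whose
    residual variance is numerically zero (x_j proportional to the
    target-projection score), reported at ``cap``.
    """
    b = model.coef
    norm = np.linalg.norm(b)
    if norm == 0:
        raise ValueError("zero regression vector; SR undefined")
    X = np.asarray(X_scaled, dtype=float)
    t_tp = X @ (b / norm)
    tt = t_tp @ t_tp
    if tt == 0:
        raise ValueError("degenerate target projection")
    p_tp = X.T @ t_tp / tt
    recon = np.outer(t_tp, p_tp)
    v_exp = (recon ** 2).sum(axis=0)
    v_res = ((X - recon) ** 2).sum(axis=0)
    scale = max(v_exp.max(), 1.0)
    capped = np.flatnonzero(v_res <= 1e-12 * scale)
    with np.errstate(divide="ignore"):
        sr = np.where(v_res > 0, v_exp / np.where(v_res > 0, v_res, 1.0), np.inf)
    sr = np.minimum(sr, cap)
    sr[capped] = cap
    for j in capped:
        logger.warning("feature index %d has zero SR residual; capped at %g", j, cap)
    return sr, list(capped)


def assign_direction(
    candidate_ids: list[str],
    table: FeatureTable,
    bio: list[BioactivitySummary],
    k: int = 5,
) -> tuple[dict[str, str], dict[str, float], dict[str, float]]:
    """Compare raw peak area between the k most and k least active samples.

    Most active = lowest IC50.  A feature is ``positive_activity`` when its
    mean area is higher in the most-active group (more of it, lower IC50);
    ties go to ``negative_activity`` with a warning.
    Returns (direction, most_active_means, least_active_means).
    """
    usable = sorted(
        (b for b in bio if b.usable and b.sample_id in set(table.nonblank_ids)),
        key=lambda b: (b.ic50_mean, b.sample_id),
    )
    if k < 1 or 2 * k > len(usable):
        raise ValueError(f"k={k} requires at least {2 * k} samples with bioactivity")
    top_ids = [b.sample_id for b in usable[:k]]          # most active
    bottom_ids = [b.sample_id for b in usable[-k:]]      # least active
    cols = table.feature_index(candidate_ids)
    top = table.areas[table.sample_index(top_ids)][:, cols].mean(axis=0)
    bottom = table.areas[table.sample_index(bottom_ids)][:, cols].mean(axis=0)
    direction = {}
    for fid, t, bm in zip(candidate_ids, top, bottom):
        if t > bm:
            direction[fid] = "positive_activity"
        else:
            if t == bm:
                logger.warning("feature %s: tied group means; direction set negative", fid)
            direction[fid] = "negative_activity"
    return (
        direction,
        dict(zip(candidate_ids, map(float, top))),
        dict(zip(candidate_ids, map(float, bottom))),
    )


def score_features(
    model: PlsModel,
    X_scaled: np.ndarray,
    feature_ids: list[str],
    table: FeatureTable,
    bio: list[BioactivitySummary],
    vip_threshold: float = 1.0,
    sr_threshold: float = 0.5,
    k: int = 5,
) -> SelectionScores:
    """Convenience wrapper: VIP + SR + direction in one SelectionScores."""
    vip = vip_scores(model)
    sr, capped = selectivity_ratio(model, X_scaled)
    direction, top, bottom = assign_direction(feature_ids, table, bio, k=k)
    return SelectionScores(
        feature_ids=list(feature_ids), vip=vip, sr=sr,
        vip_threshold=vip_threshold, sr_threshold=sr_threshold,
        direction=direction, sr_capped=[feature_ids[j] for j in capped],
        top_means=top, bottom_means=bottom,
    )


def select_candidates(
    scores: SelectionScores,
    table: FeatureTable,
    mode: str = "union",
    lasso_coefs: dict[str, float] | None = None,
    filters_passed: tuple[str, ...] = (),
) -> CandidateReport:
    """Build the candidate report from importance scores.

    ``mode``: "union" (default; SR-passing plus VIP-passing features),
    "intersection", "sr_only" or "vip_only".
    """
    if not scores.feature_ids:
        raise ValueError("no scored features")
    by_sr = set(np.flatnonzero(scores.passes_sr))
    by_vip = set(np.flatnonzero(scores.passes_vip))
    chosen = {
        "union": by_sr | by_vip,
        "intersection": by_sr & by_vip,
        "sr_only": by_sr,
        "vip_only": by_vip,
    }.get(mode)
    if chosen is None:
        raise ValueError(f"unknown selection mode {mode!r}")
    lasso_coefs = lasso_coefs or {}
    fidx = {f: i for i, f in enumerate(table.feature_ids)}
    candidates = []
    for j in sorted(chosen):
        fid = scores.feature_ids[j]
        i = fidx[fid]
        candidates.append(
            Candidate(
                feature_id=fid,
                mz=float(table.mz[i]),
                rt=float(table.rt[i]),
                vip=float(scores.vip[j]),
                sr=float(scores.sr[j]),
                direction=scores.direction[fid],
                lasso_coef=float(lasso_coefs.get(fid, 0.0)),
                filters_passed=filters_passed,
            )
        )
    return CandidateReport(candidates=candidates)
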