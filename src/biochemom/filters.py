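"""Feature-reduction filters applied to raw peak areas before modeling.

Two bespoke filters reduce an aligned untargeted feature list to features
plausibly biological and shared across material sources:

* blank filter — keep a feature only if its area exceeds ``fold`` times the
  mean blank-injection area in at least ``min_samples`` non-blank samples;
* source-presence filter — keep a feature present in every sample, or
  present in at least half of each (default) source group.

Both operate on *raw* areas: fold-change and presence thresholds are
meaningless after row normalization.  An audit step computes the Pearson
correlation of every removed feature with ln IC50 to confirm no plausibly
active feature was discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .bioassay import BioactivitySummary
from .core_io import FeatureTable, SampleMetadata
from .preprocess import DEFAULT_EPSILON

logger = logging.getLogger(__name__)

__all__ = [
    "FilterTrace",
    "AuditReport",
    "blank_filter",
    "source_presence_filter",
    "default_min_samples",
    "audit_removed",
]


@dataclass
class FilterTrace:
    """Ledger entry for one filter pass (inputs, survivors, reasons)."""

    name: str
    features_in: int
    features_out: int
    removed: dict[str, str]               # feature_id -> reason
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.features_out == self.features_in - len(self.removed)

    @property
    def percent_removed(self) -> float:
        return 100.0 * len(self.removed) / self.features_in if self.features_in else 0.0


@dataclass
class AuditReport:
    feature_ids: list[str]
    r: np.ndarray                 # Pearson r vs ln IC50; NaN when undefined
    n_used: int
    flagged: list[str]            # |r| >= threshold: possibly discarded actives
    r_threshold: float

    @property
    def max_abs_r(self) -> float:
        finite = self.r[np.isfinite(self.r)]
        return float(np.max(np.abs(finite))) if finite.size else math.nan


def default_min_samples(meta: list[SampleMetadata]) -> int:
    """Half (ceiling) of the smaller source group among non-blank samples."""
    sizes: dict[str, int] = {}
    for m in meta:
        if not m.is_blank:
            sizes[m.source_group] = sizes.get(m.source_group, 0) + 1
    if not sizes:
        raise ValueError("no non-blank samples in metadata")
    return math.ceil(min(sizes.values()) / 2)


def blank_filter(
    table: FeatureTable,
    fold: float = 5.0,
    min_samples: int = 8,
) -> tuple[FeatureTable, FilterTrace]:
    """Keep features whose area beats fold x mean(blank) in enough samples.

    The blank mean is taken over all blank injections per feature, zeros
    included; a feature absent from the blanks (mean 0) counts any positive
    sample area as above threshold.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if not table.blank_ids:
        raise ValueError(
            "no blank injections in the table; skip the blank filter explicitly "
            "rather than running it without blanks"
        )
    blank_idx = table.sample_index(sorted(table.blank_ids))
    sample_idx = table.sample_index(table.nonblank_ids)
    blank_mean = table.areas[blank_idx].mean(axis=0)
    above = table.areas[sample_idx] > fold * blank_mean
    counts = above.sum(axis=0)
    keep = counts >= min_samples
    removed = {
        table.feature_ids[j]: (
            f"area > {fold:g}x blank mean in only {counts[j]} sample(s) "
            f"(needed {min_samples})"
        )
        for j in np.flatnonzero(~keep)
    }
    trace = FilterTrace(
        name="blank_filter",
        features_in=table.n_features,
        features_out=int(keep.sum()),
        removed=removed,
        parameters={"fold": fold, "min_samples": min_samples},
    )
    return table.subset_features(np.flatnonzero(keep)), trace


def source_presence_filter(
    table: FeatureTable,
    meta: list[SampleMetadata],
    presence_threshold: float = DEFAULT_EPSILON,
    mode: str = "each-group",
) -> tuple[FeatureTable, FilterTrace]:
    """Keep features present everywhere or in >= half of the source groups.

    "Present" means area strictly greater than ``presence_threshold`` (the
    zero-replacement epsilon, so replaced zeros do not count).  Retention =
    (present in every non-blank sample) OR (present in >= ceil(half) of
    each group — ``mode='each-group'`` — or of at least one group —
    ``mode='any-group'``).
    """
    if mode not in ("each-group", "any-group"):
        raise ValueError(f"unknown mode {mode!r}")
    groups: dict[str, list[str]] = {}
    for m in meta:
        if not m.is_blank and m.sample_id in set(table.sample_ids):
            groups.setdefault(m.source_group, []).append(m.sample_id)
    if len(groups) < 2:
        raise ValueError("source filter needs at least 2 source groups")
    for g, ids in groups.items():
        if not ids:
            raise ValueError(f"source group {g!r} has no samples")

    nonblank_idx = table.sample_index(table.nonblank_ids)
    present_all = np.all(
        table.areas[nonblank_idx] > presence_threshold, axis=0
    )
    half_ok = []
    for g, ids in sorted(groups.items()):
        idx = table.sample_index(ids)
        count = (table.areas[idx] > presence_threshold).sum(axis=0)
        half_ok.append(count >= math.ceil(len(ids) / 2))
    half_ok = np.array(half_ok)
    group_clause = half_ok.all(axis=0) if mode == "each-group" else half_ok.any(axis=0)
    keep = present_all | group_clause

    removed = {
        table.feature_ids[j]: (
            "absent from some sample and below half-presence in "
            + ("a group" if mode == "each-group" else "every group")
        )
        for j in np.flatnonzero(~keep)
    }
    trace = FilterTrace(
        name="source_presence_filter",
        features_in=table.n_features,
        features_out=int(keep.sum()),
        removed=removed,
        parameters={
            "presence_threshold": presence_threshold,
            "mode": mode,
            "group_sizes": {g: len(ids) for g, ids in sorted(groups.items())},
        },
    )
    return table.subset_features(np.flatnonzero(keep)), trace


def audit_removed(
    removed_ids: list[str],
    table: FeatureTable,
    bio: list[BioactivitySummary],
    r_threshold: float = 0.5,
) -> AuditReport:
    """Pearson r of each removed feature's raw areas against ln IC50.

    Flags removed features with |r| >= ``r_threshold`` as possibly
    discarded actives.  Constant area vectors have undefined r and are
    reported as NaN, not flagged.
    """
    usable = {b.sample_id: b.log_ic50 for b in bio if b.usable}
    ids = [s for s in table.nonblank_ids if s in usable]
    if len(ids) < 3:
        raise ValueError("need >= 3 samples with both areas and log IC50")
    y = np.array([usable[s] for s in ids])
    X = table.areas[table.sample_index(ids)][:, table.feature_index(removed_ids)]

    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / np.where(denom > 0, denom, 1.0), np.nan)
    flagged = [
        fid for fid, rv in zip(removed_ids, r) if np.isfinite(rv) and abs(rv) >= r_threshold
    ]
    for fid in flagged:
        logger.warning("removed feature %s correlates with ln IC50 (|r| >= %g)",
                       fid, r_threshold)
    return AuditReport(
        feature_ids=list(removed_ids), r=r, n_used=len(ids),
        flagged=flagged, r_threshold=r_threshold,
    )
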