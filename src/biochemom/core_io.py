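"""Readers, writers and validation for the on-disk artifacts.

The package consumes an *aligned* untargeted-metabolomics feature table
(features as rows on disk, one peak-area column per LC-MS injection),
sample metadata, bioassay plate data, and MGF tandem spectra.  In memory
the feature table is held samples x features so the modeling code works
in the conventional n x p orientation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "Spectrum",
    "Candidate",
    "CandidateReport",
    "ValidationError",
    "load_dataset",
    "load_feature_table",
    "load_metadata",
    "load_bioassay",
    "load_spectra",
    "write_feature_table",
    "write_candidate_report",
]


class ValidationError(ValueError):
    """An input violates a dataset invariant (duplicate ids, negative areas ...)."""


@dataclass
class FeatureTable:
    """Aligned peak-area matrix plus feature/sample identity.

    ``areas`` is n_samples x n_features, raw peak-area units, >= 0.
    ``blank_ids`` flags solvent-blank injections among ``sample_ids``.
    """

    feature_ids: list[str]
    mz: np.ndarray          # Da, one per feature
    rt: np.ndarray          # minutes, one per feature
    sample_ids: list[str]
    areas: np.ndarray       # (n_samples, n_features)
    blank_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.blank_ids = frozenset(self.blank_ids)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, p = len(self.sample_ids), len(self.feature_ids)
        if self.areas.shape != (n, p):
            raise ValidationError(
                f"area matrix shape {self.areas.shape} != (n_samples={n}, n_features={p})"
            )
        if self.mz.shape != (p,) or self.rt.shape != (p,):
            raise ValidationError("mz/rt length does not match feature_ids")
        dup_f = _duplicates(self.feature_ids)
        if dup_f:
            raise ValidationError(f"duplicate feature_ids: {sorted(dup_f)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample_ids: {sorted(dup_s)}")
        stray = self.blank_ids - set(self.sample_ids)
        if stray:
            raise ValidationError(f"blank_ids not in sample_ids: {sorted(stray)}")
        if not np.all(np.isfinite(self.areas)):
            bad = np.argwhere(~np.isfinite(self.areas))[0]
            raise ValidationError(
                f"non-finite area at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        if np.any(self.areas < 0):
            bad = np.argwhere(self.areas < 0)[0]
            raise ValidationError(
                f"negative area at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def nonblank_ids(self) -> list[str]:
        return [s for s in self.sample_ids if s not in self.blank_ids]

    def sample_index(self, ids: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([pos[s] for s in ids], dtype=int)

    def feature_index(self, ids: list[str]) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        return np.array([pos[f] for f in ids], dtype=int)

    def subset_features(self, keep: np.ndarray | list[str]) -> "FeatureTable":
        """New table restricted to ``keep`` (ids or integer index), order preserved."""
        if len(keep) and isinstance(next(iter(keep)), str):
            idx = self.feature_index(list(keep))
        else:
            idx = np.asarray(keep, dtype=int)
        return replace(
            self,
            feature_ids=[self.feature_ids[i] for i in idx],
            mz=self.mz[idx],
            rt=self.rt[idx],
            areas=self.areas[:, idx],
        )

    def subset_samples(self, ids: list[str]) -> "FeatureTable":
        idx = self.sample_index(ids)
        return replace(
            self,
            sample_ids=list(ids),
            areas=self.areas[idx, :],
            blank_ids=self.blank_ids & set(ids),
        )


@dataclass(frozen=True)
class SampleMetadata:
    """One row per extract: material source group, species, replicate index."""

    sample_id: str
    source_group: str
    species: str = ""
    replicate: int = 1
    is_blank: bool = False


@dataclass
class Spectrum:
    """A tandem (MS2) spectrum: precursor m/z plus fragment peak list.

    Peaks are kept sorted ascending in m/z; intensities are nonnegative.
    """

    identifier: str
    precursor_mz: float
    peaks: np.ndarray  # (n_peaks, 2): m/z Da, intensity

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if self.peaks.shape[0] < 1:
            raise ValidationError(f"spectrum {self.identifier!r} has no peaks")
        if np.any(self.peaks[:, 1] < 0):
            raise ValidationError(f"spectrum {self.identifier!r} has negative intensity")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]

    @property
    def mz_array(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity_array(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass(frozen=True)
class Candidate:
    """One prioritized feature in the final report."""

    feature_id: str
    mz: float
    rt: float
    vip: float
    sr: float
    direction: str            # "positive_activity" (lower IC50) or "negative_activity"
    lasso_coef: float
    best_match_id: str = ""
    cosine: float = float("nan")
    filters_passed: tuple[str, ...] = ()


@dataclass
class CandidateReport:
    candidates: list[Candidate]

    def sorted(self) -> list[Candidate]:
        # Deterministic: descending SR, then descending VIP, then id.
        return sorted(
            self.candidates, key=lambda c: (-c.sr, -c.vip, c.feature_id)
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_RESERVED = ("feature_id", "mz", "rt")


def load_feature_table(path, blank_ids: set[str] | None = None) -> FeatureTable:
    """Read a features-as-rows CSV (``feature_id,mz,rt,<sample>...``).

    ``blank_ids`` marks blank-injection columns; usually supplied by
    :func:`load_dataset` from the metadata ``is_blank`` flag.
    """
    df = pd.read_csv(path, dtype={"feature_id": str})
    missing = [c for c in _RESERVED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    sample_cols = [c for c in df.columns if c not in _RESERVED]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns present")
    areas = np.empty((len(sample_cols), len(df)), dtype=float)
    for j, col in enumerate(sample_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric area at row {bad[0] + 2} (feature "
                f"{df['feature_id'].iloc[bad[0]]!r}), column {col!r}"
            )
        areas[j] = vals.fillna(0.0).to_numpy()
    return FeatureTable(
        feature_ids=df["feature_id"].tolist(),
        mz=df["mz"].to_numpy(float),
        rt=df["rt"].to_numpy(float),
        sample_ids=sample_cols,
        areas=areas,
        blank_ids=frozenset(blank_ids or set()),
    )


def load_metadata(path) -> list[SampleMetadata]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    needed = {"sample_id", "source_group"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            SampleMetadata(
                sample_id=str(r["sample_id"]),
                source_group=str(r["source_group"]),
                species=str(r.get("species", "") or ""),
                replicate=int(r.get("replicate", 1) or 1),
                is_blank=_as_bool(r.get("is_blank", False)),
            )
        )
    dup = _duplicates([m.sample_id for m in rows])
    if dup:
        raise ValidationError(f"{path}: duplicate metadata sample_ids {sorted(dup)}")
    return rows


def load_dataset(
    feature_table_path,
    metadata_path,
    blank_pattern: str | None = None,
) -> tuple[FeatureTable, list[SampleMetadata]]:
    """Read and cross-validate the feature table and sample metadata.

    Blank injections are identified by the metadata ``is_blank`` flag; if
    no metadata row flags a blank, ``blank_pattern`` (a regex on sample id)
    is the fallback.  Matrix row order follows the on-disk column order.
    """
    meta = load_metadata(metadata_path)
    blanks = {m.sample_id for m in meta if m.is_blank}
    table = load_feature_table(feature_table_path)
    if not blanks and blank_pattern:
        rx = re.compile(blank_pattern)
        blanks = {s for s in table.sample_ids if rx.search(s)}
    table = replace(table, blank_ids=frozenset(blanks & set(table.sample_ids)))

    meta_ids = {m.sample_id for m in meta}
    orphan = [s for s in table.nonblank_ids if s not in meta_ids]
    if orphan:
        raise ValidationError(f"samples missing a metadata row: {orphan}")
    groups = {m.source_group for m in meta if not m.is_blank}
    if not groups:
        raise ValidationError("metadata declares no non-blank source group")
    return table, meta


def load_bioassay(path) -> pd.DataFrame:
    """Raw viability plate data: ``sample_id,dose_ug_ml,viability_pct,plate_rep``."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    needed = {"sample_id", "dose_ug_ml", "viability_pct", "plate_rep"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing bioassay columns {sorted(missing)}")
    return df


def load_spectra(mgf_path) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` objects, one per ions block.

    Blocks without peaks are skipped with a warning; peaks are sorted
    ascending in m/z on construction.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(mgf_path)) as reader:
        for i, entry in enumerate(reader):
            mzs = np.asarray(entry.get("m/z array", []), dtype=float)
            if mzs.size == 0:
                logger.warning("MGF block %d has no peaks; skipped", i)
                continue
            params = entry.get("params", {})
            pepmass = params.get("pepmass", (np.nan,))
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            ident = str(params.get("title", f"spectrum_{i}"))
            peaks = np.column_stack([mzs, np.asarray(entry["intensity array"], float)])
            spectra.append(Spectrum(identifier=ident, precursor_mz=precursor, peaks=peaks))
    if not spectra:
        logger.warning("no spectra read from %s", mgf_path)
    return spectra


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    df = pd.DataFrame({"feature_id": table.feature_ids, "mz": table.mz, "rt": table.rt})
    for i, s in enumerate(table.sample_ids):
        df[s] = table.areas[i]
    df.to_csv(path, index=False)


def write_metadata(meta: list[SampleMetadata], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "source_group": m.source_group,
                "species": m.species,
                "replicate": m.replicate,
                "is_blank": m.is_blank,
            }
            for m in meta
        ]
    ).to_csv(path, index=False)


_REPORT_COLUMNS = [
    "feature_id", "mz", "rt", "vip", "sr", "direction",
    "lasso_coef", "best_match_id", "cosine", "filters_passed",
]


def write_candidate_report(report: CandidateReport, path) -> None:
    """TSV report, rows ordered by descending SR then VIP then feature id."""
    rows = [
        {
            "feature_id": c.feature_id,
            "mz": c.mz,
            "rt": c.rt,
            "vip": c.vip,
            "sr": c.sr,
            "direction": c.direction,
            "lasso_coef": c.lasso_coef,
            "best_match_id": c.best_match_id,
            "cosine": c.cosine,
            "filters_passed": ";".join(c.filters_passed),
        }
        for c in report.sorted()
    ]
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------

def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes", "t"}
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return False
    return bool(x)
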