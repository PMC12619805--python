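"""Seeded generator of synthetic extract-panel datasets.

Emulates the statistical structure of a two-source botanical extract panel
profiled by aligned untargeted LC-MS: heavy-tailed (log-normal) peak areas,
group-dependent missingness, solvent-blank channels, a block of
blank-dominated contaminant features, and a small set of "active" spike-in
features whose abundance covaries with ln IC50 at a controlled Pearson r.
Ground-truth labels accompany every dataset so filter specificity and
end-to-end spike recovery are measurable.

The defaults describe the study conditions the workflow targets: 24 + 16
samples in two source groups, 3 blank injections, 1600 features, 4 active
spikes at |r| = 0.8 (negatively correlated with ln IC50, i.e. associated
with *increased* activity), 30 contaminants, and IC50 spanning 57-117
µg/ml on the assay's five-dose grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .bioassay import BioactivitySummary, DEFAULT_DOSES
from .core_io import FeatureTable, SampleMetadata

__all__ = ["ScenarioSpec", "GroundTruth", "generate_dataset", "generate_viability"]

_SPECIES = ("Ocimum basilicum", "Ocimum tenuiflorum", "Ocimum gratissimum")


@dataclass
class ScenarioSpec:
    """All generator knobs, with defaults fixed to the target study design."""

    n_group_a: int = 24              # e.g. greenhouse-grown materials
    n_group_b: int = 16              # e.g. consumer products (the smaller group)
    n_features: int = 1600
    n_blanks: int = 3
    n_active_spikes: int = 4
    active_target_r: float = 0.8     # |Pearson r| between spike area and ln IC50
    active_signs: tuple[int, ...] | None = None  # default: all -1 (positive activity)
    n_contaminant_spikes: int = 30
    common_fraction: float = 0.2     # background features with low missingness
    common_missingness: float = 0.05
    rare_missingness: tuple[float, float] = (0.65, 0.95)  # per feature per group
    log_area_mean: float = 13.0      # ln of typical raw peak area
    log_area_sd: float = 1.2         # spread of per-feature baselines
    log_noise_sd: float = 0.8        # within-feature sample scatter
    group_shift_sd: float = 0.7      # per-feature multiplicative batch offset (ln scale)
    ic50_range: tuple[float, float] = (57.0, 117.0)   # µg/ml
    hill_slope: float = 2.0
    viability_upper: float = 100.0   # %
    viability_lower: float = 0.0     # %
    replicate_noise_sd: float = 2.0  # % viability
    n_plate_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.active_signs is None:
            self.active_signs = tuple([-1] * self.n_active_spikes)
        self.active_signs = tuple(int(s) for s in self.active_signs)
        if len(self.active_signs) != self.n_active_spikes:
            raise ValueError("active_signs length must equal n_active_spikes")
        if not 0.0 <= self.active_target_r < 0.99:
            raise ValueError("infeasible correlation target (need |r| < 0.99)")
        total_spikes = self.n_active_spikes + self.n_contaminant_spikes
        if total_spikes > self.n_features:
            raise ValueError("spike count exceeds n_features")
        if not all(0.0 <= m < 1.0 for m in (self.common_missingness, *self.rare_missingness)):
            raise ValueError("missingness rates must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["active_signs"] = list(self.active_signs)
        d["rare_missingness"] = list(self.rare_missingness)
        d["ic50_range"] = list(self.ic50_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("active_signs", "rare_missingness", "ic50_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    active_ids: dict[str, int]       # feature_id -> sign (-1: area up when IC50 down)
    contaminant_ids: list[str]
    log_ic50: dict[str, float]       # per sample, ln µg/ml
    fourpl: dict[str, tuple[float, float, float, float]]  # lower, upper, slope, inflection


def _draw_log_ic50(spec: ScenarioSpec, sample_ids: list[str]) -> dict[str, float]:
    # Dedicated substream so the feature matrix and the viability plates
    # agree on the true potencies regardless of draw order elsewhere.
    rng = np.random.default_rng([spec.seed, 1])
    lo, hi = np.log(spec.ic50_range[0]), np.log(spec.ic50_range[1])
    vals = rng.uniform(lo, hi, size=len(sample_ids))
    return {s: float(v) for s, v in zip(sample_ids, vals)}


def _sample_ids(spec: ScenarioSpec) -> tuple[list[str], list[str], list[str]]:
    a = [f"GH{i + 1:02d}" for i in range(spec.n_group_a)]
    b = [f"CP{i + 1:02d}" for i in range(spec.n_group_b)]
    blanks = [f"BLANK{i + 1}" for i in range(spec.n_blanks)]
    return a, b, blanks


def _exact_corr_signal(x: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance vector with sample correlation exactly r against x."""
    xs = (x - x.mean()) / x.std()
    e = rng.standard_normal(x.size)
    e = e - e.mean()
    e = e - (e @ xs) / (xs @ xs) * xs          # orthogonal to xs
    e = e / e.std()
    return r * xs + np.sqrt(1.0 - r ** 2) * e


def generate_dataset(
    spec: ScenarioSpec,
) -> tuple[FeatureTable, list[SampleMetadata], list[BioactivitySummary], GroundTruth]:
    """Generate one complete panel: feature table, metadata, bioactivity, truth."""
    rng = np.random.default_rng([spec.seed, 0])
    ids_a, ids_b, blank_ids = _sample_ids(spec)
    sample_ids = ids_a + ids_b + blank_ids
    n = spec.n_group_a + spec.n_group_b
    n_total = n + spec.n_blanks
    p = spec.n_features

    log_ic50 = _draw_log_ic50(spec, ids_a + ids_b)
    y = np.array([log_ic50[s] for s in ids_a + ids_b])

    # spike placement
    positions = rng.choice(p, size=spec.n_active_spikes + spec.n_contaminant_spikes,
                           replace=False)
    active_pos = positions[: spec.n_active_spikes]
    contam_pos = positions[spec.n_active_spikes:]
    background_pos = np.setdiff1d(np.arange(p), positions)

    areas = np.zeros((n_total, p))

    # --- background: log-normal areas, group batch shift, missingness ----
    base = rng.normal(spec.log_area_mean, spec.log_area_sd, size=background_pos.size)
    shift_b = rng.normal(0.0, spec.group_shift_sd, size=background_pos.size)
    noise = rng.normal(0.0, spec.log_noise_sd, size=(n, background_pos.size))
    log_area = base[None, :] + noise
    log_area[spec.n_group_a:, :] += shift_b[None, :]
    bg = np.exp(log_area)

    is_common = rng.random(background_pos.size) < spec.common_fraction
    lo_m, hi_m = spec.rare_missingness
    miss_a = np.where(is_common, spec.common_missingness,
                      rng.uniform(lo_m, hi_m, size=background_pos.size))
    miss_b = np.where(is_common, spec.common_missingness,
                      rng.uniform(lo_m, hi_m, size=background_pos.size))
    u = rng.random((n, background_pos.size))
    missing = np.vstack([
        u[: spec.n_group_a] < miss_a[None, :],
        u[spec.n_group_a:] < miss_b[None, :],
    ])
    bg[missing] = 0.0
    areas[:n, background_pos] = bg
    # background features are absent from solvent blanks (stay 0)

    # --- active spikes: exact target correlation with ln IC50 -----------
    active_scale = np.exp(rng.normal(spec.log_area_mean, 0.5, size=spec.n_active_spikes))
    for k, j in enumerate(active_pos):
        sign = spec.active_signs[k]
        s = _exact_corr_signal(y, spec.active_target_r, rng)
        vals = active_scale[k] * (1.0 + 0.2 * np.sign(sign) * s)
        areas[:n, j] = np.maximum(vals, 1e-3 * active_scale[k])

    # --- contaminants: comparable abundance in blanks and samples -------
    contam_base = np.exp(rng.normal(spec.log_area_mean, 1.0, size=contam_pos.size))
    areas[:n, contam_pos] = contam_base[None, :] * np.exp(
        rng.normal(0.0, 0.4, size=(n, contam_pos.size))
    )
    areas[n:, contam_pos] = contam_base[None, :] * np.exp(
        rng.normal(0.0, 0.2, size=(spec.n_blanks, contam_pos.size))
    )

    feature_ids = [f"F{j + 1:04d}" for j in range(p)]
    table = FeatureTable(
        feature_ids=feature_ids,
        mz=rng.uniform(100.0, 1000.0, size=p),
        rt=rng.uniform(0.5, 16.0, size=p),
        sample_ids=sample_ids,
        areas=areas,
        blank_ids=frozenset(blank_ids),
    )

    meta = []
    species = list(_SPECIES)
    for i, s in enumerate(ids_a):
        meta.append(SampleMetadata(s, "greenhouse", species[i % 3], i // 3 + 1))
    for i, s in enumerate(ids_b):
        meta.append(SampleMetadata(s, "consumer", species[i % 3], i // 3 + 1))
    for s in blank_ids:
        meta.append(SampleMetadata(s, "blank", "", 1, is_blank=True))

    bio = [
        BioactivitySummary(
            sample_id=s,
            ic50_mean=float(np.exp(log_ic50[s])),
            ic50_sd=0.0,
            log_ic50=log_ic50[s],
            n_replicates=spec.n_plate_reps,
        )
        for s in ids_a + ids_b
    ]

    truth = GroundTruth(
        active_ids={feature_ids[j]: spec.active_signs[k]
                    for k, j in enumerate(active_pos)},
        contaminant_ids=[feature_ids[j] for j in sorted(contam_pos)],
        log_ic50=log_ic50,
        fourpl={
            s: (spec.viability_lower, spec.viability_upper, spec.hill_slope,
                float(np.exp(log_ic50[s])))
            for s in ids_a + ids_b
        },
    )
    return table, meta, bio, truth


def generate_viability(spec: ScenarioSpec) -> pd.DataFrame:
    """Raw viability plate rows on the five-dose assay grid.

    Each sample gets ``n_plate_reps`` replicate wells per dose; the true
    inflection of each sample's 4PL is its IC50 (lower = 0, upper = 100, so
    the 50% crossing coincides with the inflection), plus Gaussian
    replicate noise in % viability.
    """
    rng = np.random.default_rng([spec.seed, 2])
    ids_a, ids_b, _ = _sample_ids(spec)
    log_ic50 = _draw_log_ic50(spec, ids_a + ids_b)
    rows = []
    doses = np.asarray(DEFAULT_DOSES)
    lo, up, slope = spec.viability_lower, spec.viability_upper, spec.hill_slope
    for s in ids_a + ids_b:
        c = np.exp(log_ic50[s])
        clean = np.full_like(doses, up)
        pos = doses > 0
        clean[pos] = lo + (up - lo) / (1.0 + (doses[pos] / c) ** slope)
        for rep in range(1, spec.n_plate_reps + 1):
            noisy = clean + rng.normal(0.0, spec.replicate_noise_sd, size=doses.size)
            for d, v in zip(doses, noisy):
                rows.append(
                    {"sample_id": s, "dose_ug_ml": float(d),
                     "viability_pct": float(v), "plate_rep": rep}
                )
    return pd.DataFrame(rows, columns=["sample_id", "dose_ug_ml", "viability_pct", "plate_rep"])
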