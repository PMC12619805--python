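"""End-to-end orchestration of the biochemometric workflow.

Order of operations (fixed, matching the stepwise-filtration design):

    zero replacement -> zero-variance removal -> blank filter ->
    source-presence filter -> Pearson audit of removed features ->
    Hellinger transform -> balanced 80:20 split -> train-fitted
    auto-scaling -> LASSO preselection (LOO-CV lambda) -> PLS1 on the
    selected features (LOO-CV component count) -> VIP + Selectivity Ratio
    -> direction of effect -> candidate report.

A stage ledger optionally refits and validates the PLS model after each
filtration stage so the incremental value of every filter is visible as a
train/test RMSE pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bioassay import BioactivitySummary
from .core_io import CandidateReport, FeatureTable, SampleMetadata
from .filters import (
    AuditReport, FilterTrace, audit_removed, blank_filter,
    default_min_samples, source_presence_filter,
)
from .models import (
    LassoFit, PlsModel, SplitPlan, ValidationResult, balanced_split,
    cv_percent, fit_pls_model, lasso_select_loo, pls_predict, rmse,
)
from .preprocess import (
    DEFAULT_EPSILON, apply_scaler, drop_zero_variance, hellinger, replace_zeros,
)
from .selection import SelectionScores, score_features, select_candidates

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    epsilon: float = DEFAULT_EPSILON
    blank_fold: float = 5.0
    min_samples: int | None = None        # None -> half the smaller source group
    presence_mode: str = "each-group"
    audit_r_threshold: float = 0.5
    test_fraction: float = 0.2
    split_seed: int = 0
    max_components: int = 10
    vip_threshold: float = 1.0
    sr_threshold: float = 0.5
    selection_mode: str = "union"
    top_k: int = 5
    stage_models: bool = False            # refit/validate PLS after each stage


@dataclass
class PipelineResult:
    traces: list[FilterTrace]
    audit: AuditReport | None
    split: SplitPlan
    lasso: LassoFit
    model: PlsModel
    validation: ValidationResult
    scores: SelectionScores
    report: CandidateReport
    stage_validations: dict[str, ValidationResult] = field(default_factory=dict)
    selected_feature_ids: list[str] = field(default_factory=list)
    filtered_table: FeatureTable | None = None

    @property
    def feature_counts(self) -> dict[str, int]:
        counts = {}
        if self.traces:
            counts["input"] = self.traces[0].features_in
            for t in self.traces:
                counts[t.name] = t.features_out
        counts["lasso"] = len(self.selected_feature_ids)
        counts["candidates"] = len(self.report.candidates)
        return counts


def _validate_stage(
    X_raw_by_sample: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    sample_ids: list[str],
    max_components: int,
    epsilon: float,
) -> ValidationResult:
    """Hellinger -> train-scaled PLS with LOO component choice -> test RMSE."""
    H = hellinger(X_raw_by_sample)
    Ht, Hs = H[train_idx], H[test_idx]
    # a feature observed in fewer than two training samples cannot be
    # cross-validated (some LOO folds see only replaced zeros, whose
    # near-zero variance blows up auto-scaled values); drop it here
    keep = (((X_raw_by_sample[train_idx] > epsilon).sum(axis=0) >= 2)
            & (np.ptp(Ht, axis=0) > 0))
    model = fit_pls_model(Ht[:, keep], y[train_idx], max_components=max_components)
    preds = pls_predict(model, Hs[:, keep])
    result = ValidationResult(
        rmse_train_cv=float(model.cv_rmse[model.n_components - 1]),
        rmse_test=rmse(y[test_idx], preds),
        cv_percent=cv_percent(rmse(y[test_idx], preds), y),
        n_components=model.n_components,
        predictions={sample_ids[i]: float(v) for i, v in zip(test_idx, preds)},
    )
    return result


def run_pipeline(
    table: FeatureTable,
    meta: list[SampleMetadata],
    bio: list[BioactivitySummary],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full workflow and return every intermediate artifact."""
    cfg = config or PipelineConfig()
    traces: list[FilterTrace] = []

    # --- preprocessing on raw areas -------------------------------------
    table0 = replace_zeros(table, cfg.epsilon)
    table0, removed_const = drop_zero_variance(table0)
    if removed_const:
        traces.append(
            FilterTrace(
                name="zero_variance",
                features_in=table0.n_features + len(removed_const),
                features_out=table0.n_features,
                removed={f: "constant across samples" for f in removed_const},
            )
        )

    # --- bespoke filters -------------------------------------------------
    min_samples = cfg.min_samples if cfg.min_samples is not None else default_min_samples(meta)
    table1, trace_blank = blank_filter(table0, fold=cfg.blank_fold, min_samples=min_samples)
    traces.append(trace_blank)
    table2, trace_source = source_presence_filter(
        table1, meta, presence_threshold=cfg.epsilon, mode=cfg.presence_mode
    )
    traces.append(trace_source)

    removed_ids = list(trace_blank.removed) + list(trace_source.removed)
    audit = None
    if removed_ids:
        audit = audit_removed(removed_ids, table0, bio, r_threshold=cfg.audit_r_threshold)
        if audit.flagged:
            logger.warning("%d removed feature(s) correlate with ln IC50", len(audit.flagged))

    # --- modeled samples and split ---------------------------------------
    usable = {b.sample_id: b for b in bio if b.usable}
    modeled_ids = [s for s in table2.nonblank_ids if s in usable]
    if len(modeled_ids) < 5:
        raise ValueError("fewer than 5 samples with usable bioactivity")
    y = np.array([usable[s].log_ic50 for s in modeled_ids])
    split = balanced_split(
        [usable[s] for s in modeled_ids], test_fraction=cfg.test_fraction,
        seed=cfg.split_seed,
    )
    pos = {s: i for i, s in enumerate(modeled_ids)}
    train_idx = np.array([pos[s] for s in split.train_ids])
    test_idx = np.array([pos[s] for s in split.test_ids])

    sample_rows = table2.sample_index(modeled_ids)
    areas2 = table2.areas[sample_rows]

    # --- optional per-stage validation ledger ----------------------------
    stage_validations: dict[str, ValidationResult] = {}
    if cfg.stage_models:
        for name, tab in (("no_filter", table0), ("blank_filter", table1),
                          ("source_filter", table2)):
            stage_validations[name] = _validate_stage(
                tab.areas[tab.sample_index(modeled_ids)], y, train_idx, test_idx,
                modeled_ids, cfg.max_components, cfg.epsilon,
            )

    # --- Hellinger + train-fitted scaling --------------------------------
    H = hellinger(areas2, modeled_ids)
    keep = ((areas2[train_idx] > cfg.epsilon).any(axis=0)
            & (np.ptp(H[train_idx], axis=0) > 0))
    H = H[:, keep]
    kept_ids = [f for f, k in zip(table2.feature_ids, keep) if k]

    # --- LASSO preselection (scaler re-fit per LOO fold inside) ----------
    lasso = lasso_select_loo(H[train_idx], y[train_idx])
    sel = lasso.nonzero
    if not sel:
        raise ValueError("LASSO selected no features; cannot build the sparse PLS model")
    selected_ids = [kept_ids[j] for j in sel]
    logger.info("LASSO selected %d of %d features", len(sel), len(kept_ids))

    if cfg.stage_models:
        lasso_pred = (apply_scaler(H[test_idx], lasso.scaler) @ lasso.selected_coef
                      + lasso.y_mean)
        stage_validations["lasso_direct"] = ValidationResult(
            rmse_train_cv=float(np.sqrt(lasso.cv_mse[
                int(np.argmin(np.abs(lasso.lambda_path - lasso.selected_lambda)))])),
            rmse_test=rmse(y[test_idx], lasso_pred),
            cv_percent=cv_percent(rmse(y[test_idx], lasso_pred), y),
            n_components=0,
            predictions={s: float(v) for s, v in zip(split.test_ids, lasso_pred)},
        )

    # --- final sparse PLS on the selected columns -------------------------
    Hsel = H[:, sel]
    model = fit_pls_model(
        Hsel[train_idx], y[train_idx], feature_ids=selected_ids,
        max_components=cfg.max_components,
    )
    preds_test = pls_predict(model, Hsel[test_idx])
    validation = ValidationResult(
        rmse_train_cv=float(model.cv_rmse[model.n_components - 1]),
        rmse_test=rmse(y[test_idx], preds_test),
        cv_percent=cv_percent(rmse(y[test_idx], preds_test), y),
        n_components=model.n_components,
        predictions={s: float(v) for s, v in zip(split.test_ids, preds_test)},
    )
    if cfg.stage_models:
        stage_validations["lasso_pls"] = validation

    # --- importance scoring and the report --------------------------------
    X_train_scaled = apply_scaler(Hsel[train_idx], model.x_scaler)
    bio_modeled = [usable[s] for s in modeled_ids]
    scores = score_features(
        model, X_train_scaled, selected_ids, table2, bio_modeled,
        vip_threshold=cfg.vip_threshold, sr_threshold=cfg.sr_threshold, k=cfg.top_k,
    )
    lasso_coef_map = {kept_ids[j]: float(lasso.selected_coef[j]) for j in sel}
    report = select_candidates(
        scores, table2, mode=cfg.selection_mode, lasso_coefs=lasso_coef_map,
        filters_passed=("blank_filter", "source_presence_filter", "lasso"),
    )

    return PipelineResult(
        traces=traces, audit=audit, split=split, lasso=lasso, model=model,
        validation=validation, scores=scores, report=report,
        stage_validations=stage_validations, selected_feature_ids=selected_ids,
        filtered_table=table2,
    )
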