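"""Supervised modeling: balanced splitting, NIPALS PLS1, LASSO, validation.

The regression target throughout is ln IC50.  The chain is:

1. stratified 80:20 train/test split balanced on ln IC50 (above/below mean);
2. auto-scaling fitted on the training set only;
3. L1-penalized (LASSO) preselection with leave-one-out CV over a shared
   lambda path, coordinate descent with soft-thresholding;
4. PLS1 regression (NIPALS with deflation) on the selected features, the
   component count chosen by leave-one-out CV with full per-fold refits
   (scaler included, so no information leaks from the held-out sample);
5. RMSE on the ln IC50 scale, also expressed as a percent of the observed
   ln IC50 range (CV%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bioassay import BioactivitySummary
from .preprocess import ScalerState, apply_scaler, fit_scaler

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "PlsModel",
    "LassoFit",
    "ValidationResult",
    "balanced_split",
    "pls_nipals",
    "pls_fit",
    "select_components_loo",
    "fit_pls_model",
    "pls_predict",
    "rmse",
    "cv_percent",
    "make_lambda_grid",
    "lasso_path",
    "lasso_fit",
    "lasso_select_loo",
]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    strata: dict[str, str]        # sample_id -> "above" | "below"
    seed: int


def balanced_split(
    bio: list[BioactivitySummary],
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Stratified random split balanced on ln IC50.

    Samples are stratified above/below the mean ln IC50; test members are
    drawn uniformly (seeded) within each stratum.  Per-stratum test counts
    start from floor(fraction x stratum size) and the remainder needed to
    reach round(fraction x n) is assigned by largest fractional part
    (ties to the larger stratum, then lexicographic label).
    """
    usable = [b for b in bio if b.usable]
    if len(usable) < 5:
        raise ValueError("need at least 5 usable samples to split")
    if not 0.0 < test_fraction < 0.5:
        raise ValueError("test_fraction must be in (0, 0.5)")
    y = np.array([b.log_ic50 for b in usable])
    mean = y.mean()
    strata = {b.sample_id: ("above" if b.log_ic50 > mean else "below") for b in usable}
    members = {"above": [], "below": []}
    for b in usable:
        members[strata[b.sample_id]].append(b.sample_id)
    for label, ids in members.items():
        if len(ids) < 2:
            raise ValueError(
                f"stratum {label!r} has {len(ids)} sample(s); too small to "
                "stratify — consider a pooled split"
            )

    n_test_total = round(len(usable) * test_fraction)
    targets = {g: test_fraction * len(ids) for g, ids in members.items()}
    counts = {g: int(np.floor(t)) for g, t in targets.items()}
    leftover = n_test_total - sum(counts.values())
    order = sorted(
        members,
        key=lambda g: (-(targets[g] - counts[g]), -len(members[g]), g),
    )
    for g in order[:leftover]:
        counts[g] += 1

    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for g in sorted(members):
        ids = sorted(members[g])
        pick = rng.choice(len(ids), size=counts[g], replace=False)
        test_ids.extend(ids[i] for i in sorted(pick))
    test_set = set(test_ids)
    train_ids = [b.sample_id for b in usable if b.sample_id not in test_set]
    return SplitPlan(train_ids=train_ids, test_ids=sorted(test_ids), strata=strata, seed=seed)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS with deflation)
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """Fitted PLS1 model with the preprocessing state needed to predict."""

    n_components: int
    weights: np.ndarray          # W, p x A
    x_loadings: np.ndarray       # P, p x A
    x_scores: np.ndarray         # T, n x A
    y_loadings: np.ndarray       # q, length A
    coef: np.ndarray             # b, length p, on the scaled/centered scale
    feature_ids: list[str] = field(default_factory=list)
    x_scaler: ScalerState | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0
    cv_rmse: np.ndarray | None = None   # LOO RMSE per candidate component count


def pls_nipals(
    X: np.ndarray, y: np.ndarray, n_components: int, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core PLS1 extraction on preprocessed data.

    Per component a: w_a = X'y/||X'y||, t_a = X w_a, p_a = X't_a/(t_a't_a),
    q_a = y't_a/(t_a't_a); then deflate X and y.  Returns (W, P, T, q, b)
    with b = W (P'W)^-1 q.  Stops early (with a warning) if y becomes
    numerically orthogonal to X.
    """
    Xd = np.array(X, dtype=float)
    yd = np.array(y, dtype=float).ravel()
    n, p = Xd.shape
    A = min(n_components, n - 1 if n > 1 else 1, p)
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    a_done = 0
    for a in range(A):
        c = Xd.T @ yd
        norm = np.linalg.norm(c)
        if norm <= tol:
            logger.warning("PLS stopped at %d component(s): y orthogonal to X", a)
            break
        w = c / norm
        t = Xd @ w
        tt = t @ t
        if tt <= tol:
            logger.warning("PLS stopped at %d component(s): degenerate score", a)
            break
        pa = Xd.T @ t / tt
        qa = yd @ t / tt
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        a_done += 1
    W, P, T, q = W[:, :a_done], P[:, :a_done], T[:, :a_done], q[:a_done]
    if a_done == 0:
        b = np.zeros(p)
    else:
        b = W @ np.linalg.solve(P.T @ W, q)
    return W, P, T, q, b


def pls_fit(X_scaled: np.ndarray, y_centered: np.ndarray, max_components: int) -> PlsModel:
    """Fit PLS1 on already-scaled X and centered y (no scaler state attached)."""
    W, P, T, q, b = pls_nipals(X_scaled, y_centered, max_components)
    return PlsModel(
        n_components=W.shape[1], weights=W, x_loadings=P, x_scores=T,
        y_loadings=q, coef=b,
    )


def _loo_sq_errors(X_raw: np.ndarray, y: np.ndarray, n_components: int,
                   scale_method: str = "auto") -> np.ndarray:
    """Squared LOO prediction errors for each candidate A in 1..n_components.

    Each fold refits the scaler and the PLS decomposition on the n-1
    retained samples, then predicts the held-out sample at every component
    count (nested models share one NIPALS pass per fold).
    """
    n = X_raw.shape[0]
    if n < 3:
        raise ValueError("LOO selection needs at least 3 training samples")
    A_max = min(n_components, n - 2, X_raw.shape[1])
    sq = np.full((n, A_max), np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = X_raw[keep], y[keep]
        scaler = fit_scaler(Xi, scale_method)
        ym, ys = float(yi.mean()), float(yi.std(ddof=1)) or 1.0
        W, P, T, q, _ = pls_nipals(apply_scaler(Xi, scaler), (yi - ym) / ys, A_max)
        x_new = apply_scaler(X_raw[i:i + 1], scaler).ravel()
        a_done = W.shape[1]
        for a in range(1, A_max + 1):
            aa = min(a, a_done)
            if aa == 0:
                pred = ym
            else:
                b = W[:, :aa] @ np.linalg.solve(P[:, :aa].T @ W[:, :aa], q[:aa])
                pred = ym + ys * float(x_new @ b)
            sq[i, a - 1] = (pred - y[i]) ** 2
    return sq


def select_components_loo(
    X_raw: np.ndarray, y: np.ndarray, max_components: int = 10
) -> tuple[int, np.ndarray]:
    """Leave-one-out choice of the PLS component count.

    Returns (A*, cv_rmse) where cv_rmse[a-1] is the LOO RMSE with a
    components; A* minimizes it with a smallest-A tie-break.
    """
    sq = _loo_sq_errors(np.asarray(X_raw, float), np.asarray(y, float), max_components)
    cv = np.sqrt(sq.mean(axis=0))
    a_star = int(np.argmin(cv)) + 1  # argmin returns first (= smallest A) on ties
    return a_star, cv


def fit_pls_model(
    X_raw: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str] | None = None,
    max_components: int = 10,
    n_components: int | None = None,
    scale_method: str = "auto",
) -> PlsModel:
    """End-to-end PLS fit from unscaled (post-transform) data.

    Chooses the component count by LOO CV unless ``n_components`` is given,
    then refits scaler + PLS on the full training set.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_components is None:
        n_components, cv = select_components_loo(X_raw, y, max_components)
    else:
        cv = None
    scaler = fit_scaler(X_raw, scale_method)
    ym, ys = float(y.mean()), float(y.std(ddof=1)) or 1.0
    model = pls_fit(apply_scaler(X_raw, scaler), (y - ym) / ys, n_components)
    model.feature_ids = list(feature_ids) if feature_ids is not None else []
    model.x_scaler = scaler
    model.y_mean, model.y_scale = ym, ys
    model.cv_rmse = cv
    return model


def pls_predict(model: PlsModel, X_new_raw: np.ndarray) -> np.ndarray:
    """Predict ln IC50 for new samples on the model's feature set/order."""
    X_new_raw = np.asarray(X_new_raw, dtype=float)
    if X_new_raw.ndim == 1:
        X_new_raw = X_new_raw[None, :]
    if model.x_scaler is None:
        raise ValueError("model has no scaler state; fit with fit_pls_model")
    if X_new_raw.shape[1] != len(model.coef):
        raise ValueError(
            f"feature mismatch: model has {len(model.coef)} features, "
            f"input has {X_new_raw.shape[1]}"
        )
    Xs = apply_scaler(X_new_raw, model.x_scaler)
    return model.y_mean + model.y_scale * (Xs @ model.coef)


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    rmse_train_cv: float         # LOO RMSE on the training set, ln IC50 units
    rmse_test: float             # held-out RMSE, ln IC50 units
    cv_percent: float            # 100 * rmse_test / range of observed ln IC50
    n_components: int
    predictions: dict[str, float] = field(default_factory=dict)


def rmse(observed, predicted) -> float:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length, nonempty")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def cv_percent(rmse_value: float, observed) -> float:
    """RMSE as a percent of the observed range (max - min over the cohort)."""
    obs = np.asarray(observed, dtype=float)
    rng = float(obs.max() - obs.min())
    if rng == 0:
        raise ValueError("observed range is zero; CV% undefined")
    return 100.0 * rmse_value / rng


# ---------------------------------------------------------------------------
# LASSO (coordinate descent with soft-thresholding)
# ---------------------------------------------------------------------------

@dataclass
class LassoFit:
    lambda_path: np.ndarray          # descending
    coefs: np.ndarray                # len(path) x p
    selected_lambda: float
    selected_coef: np.ndarray        # p
    nonzero: list[int]               # column indices with |beta| > 0 at selected lambda
    cv_mse: np.ndarray | None = None # LOO mean squared error per lambda
    scaler: "ScalerState | None" = None   # set when fitted from unscaled data
    y_mean: float = 0.0


def make_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100,
                     ratio: float = 1e-4) -> np.ndarray:
    """Descending log-spaced grid from lambda_max = max|x_j'y|/n down."""
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ y)) / n)
    if lam_max == 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def _soft(z: float, g: float) -> float:
    return np.sign(z) * max(abs(z) - g, 0.0)


def _cd_kernel(G, c, lam, beta, tol, max_iter):
    """Cyclic coordinate descent on the Gram form of the LASSO objective.

    Minimizes (1/2n)||y - Xb||^2 + lam ||b||_1 given G = X'X/n, c = X'y/n.
    Converges on the current active set, then sweeps every coordinate to
    check the KKT conditions (admitting new actives); repeats until a full
    sweep moves no coefficient by more than ``tol``.
    """
    p = G.shape[0]
    grad = G @ beta  # maintained as G @ beta
    for _ in range(max_iter):
        for _ in range(max_iter):
            delta = 0.0
            for j in range(p):
                old = beta[j]
                if old == 0.0:
                    continue
                djj = G[j, j]
                if djj <= 0.0:
                    continue
                rho = c[j] - (grad[j] - djj * old)
                new = np.sign(rho) * max(abs(rho) - lam, 0.0) / djj
                if new != old:
                    beta[j] = new
                    diff = new - old
                    for k in range(p):
                        grad[k] += G[k, j] * diff
                    step = abs(diff)
                    if step > delta:
                        delta = step
            if delta <= tol:
                break
        delta_full = 0.0
        for j in range(p):
            old = beta[j]
            djj = G[j, j]
            if djj <= 0.0:
                continue
            rho = c[j] - (grad[j] - djj * old)
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / djj
            if new != old:
                beta[j] = new
                diff = new - old
                for k in range(p):
                    grad[k] += G[k, j] * diff
                step = abs(diff)
                if step > delta_full:
                    delta_full = step
        if delta_full <= tol:
            return beta
    return beta


try:  # the compiled kernel is a large speedup for LOO path refits
    from numba import njit as _njit

    _cd_kernel_fast = _njit(cache=False)(_cd_kernel)
except Exception:  # pragma: no cover - numba unavailable
    _cd_kernel_fast = _cd_kernel


def _cd_solve(
    X: np.ndarray, y: np.ndarray, lam: float, beta: np.ndarray,
    G: np.ndarray, c: np.ndarray, tol: float = 1e-7, max_iter: int = 10_000,
) -> np.ndarray:
    return _cd_kernel_fast(G, c, float(lam), beta.copy(), float(tol), max_iter)


def lasso_path(X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray,
               tol: float = 1e-7) -> np.ndarray:
    """Warm-started coefficient path over a descending lambda grid."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in LASSO input")
    n, p = X.shape
    G = X.T @ X / n
    c = X.T @ y / n
    coefs = np.zeros((len(lambda_grid), p))
    beta = np.zeros(p)
    for k, lam in enumerate(lambda_grid):
        beta = _cd_solve(X, y, lam, beta, G, c, tol=tol)
        coefs[k] = beta
    return coefs


def lasso_fit(X: np.ndarray, y: np.ndarray,
              lambda_grid: np.ndarray | None = None) -> LassoFit:
    """Fit the LASSO path; selection across lambda is done by the caller
    (or by :func:`lasso_select_loo`).  The returned fit selects the last
    (smallest) lambda by default."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(X, y)
    coefs = lasso_path(X, y, lambda_grid)
    k = len(lambda_grid) - 1
    return LassoFit(
        lambda_path=np.asarray(lambda_grid, float),
        coefs=coefs,
        selected_lambda=float(lambda_grid[k]),
        selected_coef=coefs[k],
        nonzero=list(np.flatnonzero(coefs[k])),
    )


def lasso_select_loo(
    X_raw: np.ndarray, y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    scale_method: str = "auto",
) -> LassoFit:
    """LOO-CV lambda selection over a shared path, then a full-data refit.

    ``X_raw`` is the unscaled (post-transform) design: the scaler and the
    response centering are re-fit inside every fold, mirroring the PLS LOO.
    This is essential, not cosmetic — with p >= n, columns standardized on
    the *full* training set satisfy sum-to-zero constraints that make each
    held-out sample a linear function of its fold, so an interpolating
    (small-lambda) model "predicts" even pure noise perfectly and CV then
    prefers dense models.

    The grid is shared, computed once from the full-data scaled design;
    selected lambda = argmin mean squared error, ties to the *larger*
    lambda (sparser model).  If the refit at lambda* has no nonzero
    coefficient, fall back to the nearest lambda with at least one.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X_raw.shape[0]
    if n < 3:
        raise ValueError("LOO lambda selection needs at least 3 samples")
    full_scaler = fit_scaler(X_raw, scale_method)
    y_mean = float(y.mean())
    Xs_full = apply_scaler(X_raw, full_scaler)
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(Xs_full, y - y_mean)
    sq = np.zeros((n, len(lambda_grid)))
    for i in range(n):
        keep = np.arange(n) != i
        scaler = fit_scaler(X_raw[keep], scale_method)
        ym = y[keep].mean()
        coefs = lasso_path(apply_scaler(X_raw[keep], scaler), y[keep] - ym,
                           lambda_grid)
        x_i = apply_scaler(X_raw[i:i + 1], scaler).ravel()
        sq[i] = (coefs @ x_i + ym - y[i]) ** 2
    mse = sq.mean(axis=0)
    k_star = int(np.argmin(mse))  # grid is descending, so first min = largest lambda

    full = lasso_fit(Xs_full, y - y_mean, lambda_grid)
    coef = full.coefs[k_star]
    if not np.any(coef):
        nz_rows = np.flatnonzero(np.any(full.coefs != 0, axis=1))
        if nz_rows.size:
            k_near = int(nz_rows[np.argmin(np.abs(nz_rows - k_star))])
            logger.warning(
                "empty LASSO model at CV-selected lambda; falling back to "
                "nearest lambda with a nonzero coefficient"
            )
            k_star = k_near
            coef = full.coefs[k_star]
    return LassoFit(
        lambda_path=full.lambda_path,
        coefs=full.coefs,
        selected_lambda=float(lambda_grid[k_star]),
        selected_coef=coef,
        nonzero=list(np.flatnonzero(coef)),
        cv_mse=mse,
        scaler=full_scaler,
        y_mean=y_mean,
    )
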