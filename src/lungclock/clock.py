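"""The transcriptomic age predictor.

A LASSO regression of chronological age on standardized log2 expression,
solved by cyclic coordinate descent with soft-thresholding on the
objective

    (1/2n) * ||y - X beta||^2 + lambda * ||beta||_1 ,

with the penalty weight chosen at the minimum mean validation MSE over an
internal 5-fold cross-validation, followed by an ordinary-least-squares
refit of age on the selected genes at the raw log2 scale (so the final
coefficients read in months per log2 unit).

The coordinate update for column j with nu_j = x_j'x_j / n is

    beta_j <- S( x_j' r / n + nu_j * beta_j , lambda ) / nu_j ,

where r is the current residual and S(z, a) = sign(z) * max(|z| - a, 0).
The path over a descending lambda grid is warm-started; convergence is
declared when no coordinate update changes the objective appreciably
(max_j nu_j * dbeta_j^2 <= tol, the glmnet-style criterion, which also
terminates on the flat plateaus of nearly unpenalized over-determined
fits), and solutions can be checked against the KKT subgradient
conditions with :func:`kkt_residual`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .io import ClockModel, ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "LassoFit",
    "PredictionResult",
    "soft_threshold",
    "lasso_coordinate_descent",
    "lasso_path",
    "cv_select_lambda",
    "fit_clock",
    "predict_age",
    "kkt_residual",
    "make_lambda_grid",
]


def soft_threshold(z: float | np.ndarray, a: float):
    """S(z, a) = sign(z) * max(|z| - a, 0)."""
    return np.sign(z) * np.maximum(np.abs(z) - a, 0.0)


# ---------------------------------------------------------------------------
# Coordinate descent core (optionally numba-jitted)


def _cd_update(X, r, beta, col_nn, lam, n, j):
    # explicit loops keep the summation order fixed => bitwise-reproducible
    nu = col_nn[j]
    bj = beta[j]
    z = 0.0
    for i in range(n):
        z += X[i, j] * r[i]
    z = z / n + nu * bj
    bnew = math.copysign(max(abs(z) - lam, 0.0), z) / nu
    if bnew != bj:
        d = bj - bnew
        for i in range(n):
            r[i] += X[i, j] * d
        beta[j] = bnew
        return nu * (bnew - bj) ** 2
    return 0.0


def _make_sweeps(update):
    def _cd_sweeps(X, y, beta, col_nn, lam, tol, max_iter):
        # X is Fortran-ordered so columns are contiguous. Alternates full
        # sweeps (to admit new active coordinates) with cheap sweeps over the
        # current active set, the usual coordinate-descent acceleration.
        # Stops when no coordinate update decreases the objective by more
        # than ~tol/2 (criterion max_j nu_j * dbeta_j^2 <= tol).
        n, p = X.shape
        r = y.copy()
        for j in range(p):
            if beta[j] != 0.0:
                bj = beta[j]
                for i in range(n):
                    r[i] -= X[i, j] * bj
        total = 0
        while total < max_iter:
            # --- full sweep
            max_step = 0.0
            for j in range(p):
                if col_nn[j] <= 0.0:
                    continue
                step = update(X, r, beta, col_nn, lam, n, j)
                if step > max_step:
                    max_step = step
            total += 1
            if max_step <= tol:
                return total
            active = np.flatnonzero(beta)
            # --- active-set sweeps
            while total < max_iter:
                max_step = 0.0
                for k in range(active.size):
                    step = update(X, r, beta, col_nn, lam, n, active[k])
                    if step > max_step:
                        max_step = step
                total += 1
                if max_step <= tol:
                    break
        return -(max_iter)

    return _cd_sweeps


_cd_sweeps_py = _make_sweeps(_cd_update)

try:  # jitted kernel is a speedup; the python path is identical
    import numba

    _cd_sweeps_jit = numba.njit(cache=True, fastmath=False)(
        _make_sweeps(numba.njit(cache=True, fastmath=False)(_cd_update))
    )
except Exception:  # pragma: no cover - numba absent or broken
    _cd_sweeps_jit = None



class ConvergenceError(RuntimeError):
    def __init__(self, message: str, beta: np.ndarray):
        super().__init__(message)
        self.beta = beta


def lasso_coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-14,
    max_iter: int = 100_000,
    beta0: np.ndarray | None = None,
    use_jit: bool = True,
) -> np.ndarray:
    """Minimize (1/2n)||y - X beta||^2 + lam ||beta||_1 by cyclic descent.

    ``X`` is samples x genes (expected column-standardized for selection,
    but any finite design is accepted); ``y`` is expected centered.
    ``tol`` bounds the per-update objective change ``nu_j * dbeta_j^2``
    at convergence. Raises :class:`ConvergenceError` carrying the last
    iterate if the sweep limit is hit.
    """
    X = np.asfortranarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or response")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    col_nn = (X * X).sum(axis=0) / n
    kernel = _cd_sweeps_jit if (use_jit and _cd_sweeps_jit is not None) else _cd_sweeps_py
    sweeps = kernel(X, y, beta, col_nn, float(lam), float(tol), int(max_iter))
    if sweeps < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps", beta
        )
    return beta


def kkt_residual(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float) -> float:
    """Largest violation of the LASSO KKT subgradient conditions.

    For beta_j = 0 the gradient (1/n) x_j'r must lie in [-lam, lam]; for
    beta_j != 0 it must equal lam * sign(beta_j). Returns the max excess.
    """
    n = X.shape[0]
    g = X.T @ (y - X @ beta) / n
    active = beta != 0
    viol_zero = np.maximum(np.abs(g[~active]) - lam, 0.0)
    viol_active = np.abs(g[active] - lam * np.sign(beta[active]))
    parts = [v for v in (viol_zero, viol_active) if v.size]
    return float(max(np.max(v) for v in parts)) if parts else 0.0


def make_lambda_grid(
    X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, ratio: float = 1e-3
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to ratio*lambda_max.

    lambda_max = max_j |x_j'y| / n is the smallest penalty with an
    all-zero solution (for centered y and standardized X).
    """
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ y)) / n)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, ratio * lam_max, n_lambdas)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Warm-started solutions along a descending lambda grid.

    Returns an (n_lambdas, p) coefficient array.
    """
    p = X.shape[1]
    betas = np.empty((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = lasso_coordinate_descent(
            X, y, lam, tol=tol, max_iter=max_iter, beta0=beta
        )
        betas[i] = beta
    return betas


# ---------------------------------------------------------------------------
# Cross-validated lambda selection


@dataclass
class LassoFit:
    lambda_grid: np.ndarray
    coefficient_path: np.ndarray  # (n_lambdas, p) on the full data
    cv_mse_mean: np.ndarray
    cv_mse_sd: np.ndarray
    lambda_min: float
    fold_assignments: np.ndarray
    seed: int


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd; zero-variance columns stay zero
    safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe, mean, sd


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> LassoFit:
    """Pick lambda at minimum mean validation MSE over k seeded folds.

    Each training fold is standardized on its own samples (validation
    columns reuse the fold's parameters). Ties in mean MSE break toward
    the larger lambda, i.e. the sparser model. ``X`` here is the raw
    samples x genes matrix; ``y`` raw ages.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= folds <= n samples, got k={k}, n={n}")
    Xs_full, _, _ = _standardize(X)
    yc_full = y - y.mean()
    if lambda_grid is None:
        lambda_grid = make_lambda_grid(Xs_full, yc_full)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(np.diff(lambda_grid) > 0):
        lambda_grid = np.sort(lambda_grid)[::-1]

    folds = np.empty(n, dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    mse = np.full((k, len(lambda_grid)), np.nan)
    for f, (tr, va) in enumerate(splitter.split(X)):
        folds[va] = f
        if len(va) < 1 or len(tr) < 2:
            raise ValueError(f"fold {f} has too few samples")
        Xtr, mean, sd = _standardize(X[tr])
        ybar = y[tr].mean()
        betas = lasso_path(Xtr, y[tr] - ybar, lambda_grid, tol=tol, max_iter=max_iter)
        Xva = (X[va] - mean) / np.where(sd > 0, sd, 1.0)
        preds = ybar + Xva @ betas.T  # (n_va, n_lambdas)
        mse[f] = ((preds - y[va][:, None]) ** 2).mean(axis=0)

    mean_mse = mse.mean(axis=0)
    sd_mse = mse.std(axis=0, ddof=1)
    best = int(np.argmin(mean_mse))  # grid descends, argmin first => larger lambda
    path = lasso_path(Xs_full, yc_full, lambda_grid, tol=tol, max_iter=max_iter)
    return LassoFit(
        lambda_grid=lambda_grid,
        coefficient_path=path,
        cv_mse_mean=mean_mse,
        cv_mse_sd=sd_mse,
        lambda_min=float(lambda_grid[best]),
        fold_assignments=folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fit / predict


@dataclass(frozen=True)
class PredictionResult:
    sample_id: str
    predicted_age_months: float
    chronological_age_months: float | None
    genes_missing_count: int

    @property
    def delta_age_months(self) -> float | None:
        if self.chronological_age_months is None:
            return None
        return self.predicted_age_months - self.chronological_age_months


def fit_clock(
    matrix: ExpressionMatrix,
    records: list[SampleMetadata],
    excluded_genes: tuple[str, ...] = (),
    k: int = 5,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-10,
) -> ClockModel:
    """LASSO selection + OLS refit on the samples in ``records``.

    Expression is standardized per gene for the selection stage only; the
    refit regresses age on the raw log2 values of the selected genes so
    that coefficients are interpretable. An empty support falls back to
    an intercept-only model; a singular refit is ridge-stabilized.
    """
    if excluded_genes:
        matrix = matrix.drop_genes(excluded_genes)
    sample_ids = [r.sample_id for r in records]
    sub = matrix.subset_samples(sample_ids)
    y = np.array([r.age_months for r in records], dtype=float)
    if len(set(y)) < 2:
        raise ValueError("training samples need >= 2 distinct ages")
    X = sub.values.T  # samples x genes

    fit = cv_select_lambda(X, y, k=k, lambda_grid=lambda_grid, seed=seed, tol=tol)
    i_best = int(np.argmin(np.abs(fit.lambda_grid - fit.lambda_min)))
    support = np.flatnonzero(fit.coefficient_path[i_best] != 0)

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    std_params = {
        g: (float(mean[j]), float(sd[j])) for j, g in enumerate(matrix.gene_ids)
    }

    if support.size == 0:
        logger.warning("empty LASSO support at lambda_min; intercept-only model")
        return ClockModel(
            intercept=float(y.mean()),
            coefficients={},
            lambda_selected=fit.lambda_min,
            training_gene_universe=list(matrix.gene_ids),
            training_sample_count=len(records),
            standardization_params=std_params,
            lambda_grid=[float(v) for v in fit.lambda_grid],
        )

    Xr = np.column_stack([np.ones(len(y)), X[:, support]])
    gram = Xr.T @ Xr
    rank = np.linalg.matrix_rank(gram)
    if rank < Xr.shape[1]:
        logger.warning("singular OLS refit; applying ridge stabilization")
        coef = np.linalg.solve(gram + 1e-8 * np.eye(Xr.shape[1]), Xr.T @ y)
    else:
        coef, *_ = np.linalg.lstsq(Xr, y, rcond=None)

    coefficients = {
        matrix.gene_ids[j]: float(c)
        for j, c in zip(support, coef[1:])
        if c != 0.0
    }
    return ClockModel(
        intercept=float(coef[0]),
        coefficients=coefficients,
        lambda_selected=fit.lambda_min,
        training_gene_universe=list(matrix.gene_ids),
        training_sample_count=len(records),
        standardization_params=std_params,
        lambda_grid=[float(v) for v in fit.lambda_grid],
    )


def predict_age(
    model: ClockModel,
    matrix: ExpressionMatrix,
    records: list[SampleMetadata] | None = None,
    missing_policy: str = "impute_training_mean",
    missing_threshold: float = 0.2,
) -> list[PredictionResult]:
    """Apply the clock: predicted = intercept + sum coef_g * x_gs.

    Model genes absent from ``matrix`` are imputed at their training mean
    (policy ``impute_training_mean``) as long as the missing fraction does
    not exceed ``missing_threshold``; policy ``error`` rejects any gap.
    """
    model_genes = model.gene_ids
    present = [g for g in model_genes if g in set(matrix.gene_ids)]
    missing = [g for g in model_genes if g not in set(matrix.gene_ids)]
    if model_genes:
        frac = len(missing) / len(model_genes)
        if missing and (missing_policy == "error" or frac > missing_threshold):
            raise ValueError(
                f"{len(missing)}/{len(model_genes)} model genes missing "
                f"from matrix: {missing[:10]}"
            )

    base = model.intercept
    for g in missing:
        base += model.coefficients[g] * model.training_mean(g)
    preds = np.full(len(matrix.sample_ids), base)
    for g in present:
        preds = preds + model.coefficients[g] * matrix.gene_row(g)

    ages = {r.sample_id: r.age_months for r in (records or [])}
    return [
        PredictionResult(
            sample_id=s,
            predicted_age_months=float(preds[i]),
            chronological_age_months=ages.get(s),
            genes_missing_count=len(missing),
        )
        for i, s in enumerate(matrix.sample_ids)
    ]
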