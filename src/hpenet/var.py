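"""Vector autoregressive modelling of the HF series.

Covers specification/simulation of stable VAR processes, information-criterion
order selection (BIC-preferred), the lagged regressor stack, OLS estimation,
and the sparse LASSO identification with blocked cross-validated selection of
the per-row regularization strength.  The L1 penalty drives non-significant
coefficients to exactly zero, so the fitted coefficient support *is* the
directed HF network passed on to the transfer-entropy stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .neurometrics import HF_NAMES, HFSeries

__all__ = [
    "VARModel",
    "RegressorStack",
    "LassoFitReport",
    "OrderSelection",
    "LambdaSelection",
    "default_lambda_grid",
    "simulate_var",
    "select_order",
    "build_regressors",
    "fit_var_ols",
    "select_lambda",
    "fit_var_lasso",
]

#: Coefficients smaller than this in magnitude are treated as structural zeros.
ZERO_SNAP = 1e-10


@dataclass
class VARModel:
    """VAR(p) process X(t) = sum_k A_k X(t-k) + W(t), cov(W) = Sigma.

    ``A`` has shape (p, N, N) with ``A[k-1][j, i]`` the effect of process i at
    lag k on process j.  ``Sigma`` is the innovation covariance.
    """

    A: np.ndarray
    Sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError("A must have shape (p, N, N)")
        n = self.A.shape[1]
        if self.Sigma.shape != (n, n):
            raise ValueError("Sigma must be N x N")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        if np.linalg.eigvalsh(self.Sigma).min() < -1e-10:
            raise ValueError("Sigma must be positive semi-definite")

    @property
    def n_processes(self) -> int:
        return self.A.shape[1]

    @property
    def order(self) -> int:
        return self.A.shape[0]

    def companion(self) -> np.ndarray:
        """(N*p) x (N*p) companion form [[A1..Ap], [I 0 ..], ...]."""
        n, p = self.n_processes, self.order
        top = self.A.transpose(1, 0, 2).reshape(n, n * p)
        if p == 1:
            return top
        lower = np.eye(n * (p - 1), n * p)
        return np.vstack([top, lower])

    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.companion())).max())

    def is_stable(self, tol: float = 0.0) -> bool:
        return self.spectral_radius() < 1.0 - tol

    def support(self, threshold: float = ZERO_SNAP) -> np.ndarray:
        """Directed adjacency: (i, j) True iff any lag coefficient i -> j is
        non-zero (diagonal forced False)."""
        sup = (np.abs(self.A) > threshold).any(axis=0).T  # A[k][j,i] -> (i,j)
        np.fill_diagonal(sup, False)
        return sup

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "n_processes": self.n_processes,
            "order": self.order,
            "A": self.A.tolist(),
            "Sigma": self.Sigma.tolist(),
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "VARModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            A=np.array(payload["A"]),
            Sigma=np.array(payload["Sigma"]),
            meta=payload.get("meta", {}),
        )


@dataclass
class RegressorStack:
    """Lagged design matrix Z and aligned targets.

    Row for time t stacks [X(t-1), X(t-2), ..., X(t-p)]; column k*N + i holds
    process i at lag k+1.  ``times`` records the absolute target index t of
    each row (t = p .. L-1), used by the blocked CV to drop rows that
    straddle fold boundaries.
    """

    Z: np.ndarray
    targets: np.ndarray
    times: np.ndarray
    order: int


@dataclass
class OrderSelection:
    p: int
    p_aic: int
    p_bic: int
    candidates: np.ndarray
    aic: np.ndarray
    bic: np.ndarray


@dataclass
class LambdaSelection:
    lambda_per_row: np.ndarray
    grid: np.ndarray
    cv_mse: np.ndarray  # (len(grid), N) mean held-out squared error
    n_folds: int


@dataclass
class LassoFitReport:
    lambda_per_row: np.ndarray
    nonzero_counts: np.ndarray
    selected_p: int
    lt_ratio: float
    cv_mse_curve: np.ndarray = None
    grid: np.ndarray = None


def default_lambda_grid(low: float = 1e-5, high: float = 1e3, size: int = 50) -> np.ndarray:
    """Log-spaced regularization grid, 50 points from 1e-5 to 1e3."""
    return np.logspace(np.log10(low), np.log10(high), size)


def simulate_var(
    model: VARModel, L: int, seed: int, burn_in: int = 500, names=None
) -> HFSeries:
    """Draw L samples from a stable VAR with Gaussian innovations.

    Burn-in samples are discarded so the output is (approximately) a draw
    from the stationary distribution; identical seeds give identical output.
    """
    if not model.is_stable():
        raise ValueError(
            f"model is unstable (spectral radius {model.spectral_radius():.3f} >= 1); "
            "refusing to simulate"
        )
    n, p = model.n_processes, model.order
    if L <= p:
        raise ValueError(f"L ({L}) must exceed the model order ({p})")
    rng = np.random.default_rng(seed)
    total = L + burn_in
    chol = np.linalg.cholesky(model.Sigma + 1e-15 * np.eye(n))
    w = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total + p, n))
    for t in range(p, total + p):
        acc = w[t - p]
        for k in range(p):
            acc = acc + model.A[k] @ x[t - 1 - k]
        x[t] = acc
    out = x[p + burn_in :].T
    if names is None:
        names = HF_NAMES if n == len(HF_NAMES) else tuple(f"x{i+1}" for i in range(n))
    return HFSeries(values=out, names=names)


def build_regressors(series: HFSeries, p: int) -> RegressorStack:
    """Stack lagged observations into the (L-p) x (N*p) design matrix."""
    if p < 1:
        raise ValueError("model order p must be >= 1")
    series.require_gap_free("building regressors")
    L = series.n_samples
    if p >= L:
        raise ValueError(f"order p={p} must be smaller than series length L={L}")
    X = series.values.T  # (L, N)
    blocks = [X[p - k : L - k] for k in range(1, p + 1)]
    Z = np.hstack(blocks)
    return RegressorStack(Z=Z, targets=X[p:], times=np.arange(p, L), order=p)


def _coefs_to_A(B: np.ndarray, n: int, p: int) -> np.ndarray:
    """Partition the (N, N*p) stacked coefficient matrix into p lag blocks."""
    return B.reshape(n, p, n).transpose(1, 0, 2)


def fit_var_ols(series: HFSeries, p: int) -> VARModel:
    """Ordinary least-squares VAR fit (no intercept: series are z-scored).

    Sigma is the residual covariance with denominator L - p.
    """
    series.require_gap_free("OLS fitting")
    n, L = series.n_series, series.n_samples
    if L - p <= n * p:
        raise ValueError(
            f"too few samples: need L - p > N*p, got L-p={L - p}, N*p={n * p}"
        )
    stack = build_regressors(series, p)
    coef, _, rank, _ = np.linalg.lstsq(stack.Z, stack.targets, rcond=None)
    if rank < stack.Z.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {stack.Z.shape[1]})"
        )
    resid = stack.targets - stack.Z @ coef
    sigma = resid.T @ resid / (L - p)
    return VARModel(A=_coefs_to_A(coef.T, n, p), Sigma=sigma, meta={"method": "ols", "p": p})


def select_order(series: HFSeries, p_max: int = 20) -> OrderSelection:
    """Choose the VAR order by AIC/BIC over p in {1..p_max}; BIC wins ties.

    All candidate orders are fitted on the same effective sample (the last
    L - p_max targets) so the criteria are comparable across p:
    AIC = L' ln det(Sigma_hat) + 2 N^2 p, BIC = L' ln det(Sigma_hat)
    + N^2 p ln L'.
    """
    series.require_gap_free("order selection")
    n, L = series.n_series, series.n_samples
    if L <= n * p_max + p_max:
        raise ValueError("series too short for the requested p_max")
    Leff = L - p_max
    X = series.values.T
    candidates = np.arange(1, p_max + 1)
    aic = np.empty(p_max)
    bic = np.empty(p_max)
    for idx, p in enumerate(candidates):
        blocks = [X[p_max - k : L - k] for k in range(1, p + 1)]
        Z = np.hstack(blocks)
        Y = X[p_max:]
        coef, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ coef
        sigma = resid.T @ resid / Leff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"singular residual covariance at p={p}; try a smaller p_max"
            )
        k_params = n * n * p
        aic[idx] = Leff * logdet + 2 * k_params
        bic[idx] = Leff * logdet + k_params * np.log(Leff)
    p_aic = int(candidates[np.argmin(aic)])
    p_bic = int(candidates[np.argmin(bic)])
    return OrderSelection(
        p=p_bic, p_aic=p_aic, p_bic=p_bic, candidates=candidates, aic=aic, bic=bic
    )


def _fold_of(times: np.ndarray, L: int, k: int) -> np.ndarray:
    """Fold id of each absolute time index: k contiguous blocks of equal
    length (remainder spread over the leading folds, matching array_split)."""
    bounds = np.cumsum([len(b) for b in np.array_split(np.arange(L), k)])
    return np.searchsorted(bounds, times, side="right")


def _lasso_path_mse(Ztr, Ytr, Zval, Yval, grid) -> np.ndarray:
    """Held-out squared error for every (lambda, target row); warm-started
    coordinate descent walks the grid from strongest penalty down."""
    n_tr = Ztr.shape[0]
    mse = np.empty((len(grid), Ytr.shape[1]))
    order = np.argsort(grid)[::-1]
    est = Lasso(alpha=1.0, fit_intercept=False, warm_start=True, max_iter=50_000, tol=1e-6)
    for gi in order:
        est.alpha = grid[gi] / (2 * n_tr)
        est.fit(Ztr, Ytr)
        pred = Zval @ est.coef_.T
        mse[gi] = ((Yval - pred) ** 2).mean(axis=0)
    return mse


def select_lambda(
    series: HFSeries,
    p: int,
    grid: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> LambdaSelection:
    """Blocked k-fold CV for the per-row LASSO penalty.

    The series is partitioned into k sequential, non-overlapping folds of
    equal length in original time order (no shuffling, so serial dependence
    is respected).  Regressor rows whose lag window straddles a fold
    boundary are dropped from both sides.  For each target row the grid
    value minimizing the mean held-out squared prediction error is retained.

    ``seed`` is accepted for interface uniformity; the fold layout is
    deterministic.
    """
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("lambda grid must be strictly positive")
    L = series.n_samples
    if L // k < p + 1:
        raise ValueError(
            f"folds of ~{L // k} samples are shorter than p+1={p + 1}; "
            "reduce k or the order"
        )
    stack = build_regressors(series, p)
    fold_of_target = _fold_of(stack.times, L, k)
    fold_of_oldest = _fold_of(stack.times - p, L, k)
    intact = fold_of_target == fold_of_oldest  # lag window within one fold
    n = series.n_series
    mse_sum = np.zeros((len(grid), n))
    for f in range(k):
        val = intact & (fold_of_target == f)
        train = intact & (fold_of_target != f)
        if not val.any() or not train.any():
            raise ValueError(f"fold {f} has no usable rows after boundary trimming")
        mse_sum += _lasso_path_mse(
            stack.Z[train], stack.targets[train], stack.Z[val], stack.targets[val], grid
        )
    cv_mse = mse_sum / k
    lam = grid[np.argmin(cv_mse, axis=0)]
    return LambdaSelection(lambda_per_row=lam, grid=grid, cv_mse=cv_mse, n_folds=k)


def _check_kkt(Z, y, beta, alpha, row, rtol=1e-4):
    """Verify the LASSO stationarity conditions of a returned solution:
    |g_j| <= alpha for inactive coefficients and g_j = alpha sign(beta_j) for
    active ones, with g = Z'(y - Z beta)/n.  Raises on violation."""
    n = Z.shape[0]
    g = Z.T @ (y - Z @ beta) / n
    scale = max(alpha, np.max(np.abs(Z.T @ y)) / n)
    tol = rtol * scale
    active = beta != 0
    viol = max(
        float(np.max(np.abs(g[active] - alpha * np.sign(beta[active])), initial=0.0)),
        float(np.max(np.abs(g[~active]), initial=0.0) - alpha),
    )
    if viol > tol:
        raise RuntimeError(
            f"LASSO solution for row {row} violates optimality by {viol:.2e} "
            f"(tolerance {tol:.2e}, alpha={alpha:.3g}, n={n}); increase "
            "max_iter or rescale the inputs"
        )


def fit_var_lasso(
    series: HFSeries, p: int, lambda_per_row
) -> tuple[VARModel, LassoFitReport]:
    """Sparse VAR fit: per-row L1-penalized least squares over all L-p samples.

    Row j solves  min_b ||X_j - Z b||^2 + lambda_j ||b||_1  (no intercept);
    coefficients below 1e-10 in magnitude are snapped to exact zero, the lag
    blocks A_1..A_p are recovered by partitioning the stacked coefficient
    matrix, and Sigma comes from the residuals of the sparse model.
    A scalar ``lambda_per_row`` applies one global penalty to every row.
    """
    if not series.standardized:
        warnings.warn(
            "LASSO fitting expects z-scored series so the penalty treats all "
            "processes equally",
            stacklevel=2,
        )
    n = series.n_series
    lam = np.broadcast_to(np.asarray(lambda_per_row, dtype=float), (n,)).copy()
    stack = build_regressors(series, p)
    n_obs = stack.Z.shape[0]
    coef = np.empty((n, n * p))
    with warnings.catch_warnings():
        # convergence is verified below via the KKT conditions; the solver's
        # dual-gap heuristic is unreachable in the unpenalized limit
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for j in range(n):
            alpha = lam[j] / (2 * n_obs)
            est = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000, tol=1e-8)
            est.fit(stack.Z, stack.targets[:, j])
            coef[j] = est.coef_
            _check_kkt(stack.Z, stack.targets[:, j], est.coef_, alpha, row=j)
    coef[np.abs(coef) < ZERO_SNAP] = 0.0
    resid = stack.targets - stack.Z @ coef.T
    sigma = resid.T @ resid / n_obs
    model = VARModel(
        A=_coefs_to_A(coef, n, p),
        Sigma=sigma,
        meta={"method": "lasso", "p": p, "lambda_per_row": lam.tolist()},
    )
    report = LassoFitReport(
        lambda_per_row=lam,
        nonzero_counts=(np.abs(coef) > 0).sum(axis=1),
        selected_p=p,
        lt_ratio=series.n_samples / (n * n * p),
    )
    return model, report
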