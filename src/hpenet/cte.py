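"""Analytic conditional transfer entropy from a fitted VAR.

The fitted (sparse) VAR is converted to its innovations-form state-space
representation; the innovation variance of any *sub-observed* process — the
optimal one-step predictor of a target from the past of an arbitrary subset
of processes — is then obtained by solving the discrete algebraic Riccati
equation (DARE) of the reduced observation model, with no model refitting.

For source i, target j, and conditioning set S = everything except {i, j}:

    cTE(i -> j | S) = 1/2 ln( sigma2_r / sigma2_u )

where sigma2_u is the full-model innovation variance of X_j and sigma2_r the
innovation variance when the past of X_i is withheld (S and X_j remain
observed).  Under the linear-Gaussian model this equals conditional Granger
causality, and sigma2_r >= sigma2_u guarantees non-negativity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .var import VARModel

__all__ = [
    "StateSpaceModel",
    "CTEResult",
    "BinaryAdjacency",
    "var_to_ss",
    "subobserved_innovation_variance",
    "restricted_residual_variance",
    "cte_pair",
    "bivariate_te",
    "cte_matrix",
    "cte_node",
    "binarize",
]

#: Exact-zero threshold for "a significant causal link is present".
LINK_THRESHOLD = 1e-10

#: Acceptable relative residual of the DARE solution.
DARE_RTOL = 1e-9


@dataclass
class StateSpaceModel:
    """Innovations-form state space equivalent to a VAR(p).

    z(t+1) = F z(t) + K u(t),  x(t) = C z(t) + u(t),  cov(u) = Sigma,
    with state z(t) the stacked past [x(t-1); ...; x(t-p)], F the companion
    matrix, C = [A_1 ... A_p], and Kalman gain K = [I; 0; ...; 0].
    """

    F: np.ndarray
    C: np.ndarray
    K: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self):
        m = self.F.shape[0]
        n = self.C.shape[0]
        if self.F.shape != (m, m) or self.C.shape != (n, m) or self.K.shape != (m, n):
            raise ValueError("inconsistent state-space dimensions")
        if np.linalg.eigvalsh((self.Sigma + self.Sigma.T) / 2).min() < -1e-10:
            raise ValueError("innovation covariance must be positive semi-definite")

    @property
    def n_obs(self) -> int:
        return self.C.shape[0]

    @property
    def state_dim(self) -> int:
        return self.F.shape[0]

    def autocovariance(self, n_lags: int) -> np.ndarray:
        """Output autocovariance sequence Gamma_0..Gamma_{n_lags} by solving
        the state Lyapunov equation."""
        Q = self.K @ self.Sigma @ self.K.T
        P = linalg.solve_discrete_lyapunov(self.F, Q)
        gammas = np.empty((n_lags + 1, self.n_obs, self.n_obs))
        CPC = self.C @ P @ self.C.T
        gammas[0] = CPC + self.Sigma
        Fk = np.eye(self.state_dim)
        # cov(z(t+k), u(t)) chain: z(t+k) = F^k z(t) + sum F^{k-1-m} K u(t+m)
        for k in range(1, n_lags + 1):
            FkK = np.linalg.matrix_power(self.F, k - 1) @ self.K @ self.Sigma
            Fk = Fk @ self.F
            gammas[k] = self.C @ (Fk @ P) @ self.C.T + self.C @ FkK
        return gammas


def var_to_ss(model: VARModel) -> StateSpaceModel:
    """Convert a VAR(p) to its innovations-form state space (companion
    embedding): state dimension N*p, zero state-estimation error, so the
    output process has exactly the VAR's second-order statistics."""
    n, p = model.n_processes, model.order
    F = model.companion() if p > 1 else model.A[0]
    C = model.A.transpose(1, 0, 2).reshape(n, n * p)
    K = np.zeros((n * p, n))
    K[:n, :] = np.eye(n)
    if p == 1:
        F = np.asarray(F)
    return StateSpaceModel(F=F, C=C, K=K, Sigma=model.Sigma.copy())


def _dare_residual(P, F, C, Q, R, S) -> float:
    V = C @ P @ C.T + R
    G = F @ P @ C.T + S
    rhs = F @ P @ F.T + Q - G @ np.linalg.solve(V, G.T)
    return float(np.max(np.abs(P - rhs)) / max(1.0, np.max(np.abs(P))))


def _solve_filter_dare(F, C, Q, R, S) -> np.ndarray:
    """Stationary filter DARE:  P = F P F' + Q - (F P C' + S)(C P C' + R)^-1 (.)'.

    scipy's control-form solver is tried first; a fixed-point Riccati
    iteration (always convergent for a stable F with R > 0) covers pencil
    degeneracies such as a singular companion matrix.  The solution is
    accepted only if its relative residual is below 1e-9.
    """
    P = None
    try:
        P = linalg.solve_discrete_are(F.T, C.T, Q, R, s=S)
        if _dare_residual(P, F, C, Q, R, S) > DARE_RTOL:
            P = None
    except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
        P = None
    if P is None:
        P = Q.copy()
        for _ in range(100_000):
            V = C @ P @ C.T + R
            G = F @ P @ C.T + S
            P_next = F @ P @ F.T + Q - G @ np.linalg.solve(V, G.T)
            if np.max(np.abs(P_next - P)) < 1e-14 * max(1.0, np.max(np.abs(P_next))):
                P = P_next
                break
            P = P_next
        resid = _dare_residual(P, F, C, Q, R, S)
        if resid > DARE_RTOL:
            raise np.linalg.LinAlgError(
                f"Riccati solver failed to converge (relative residual {resid:.2e}); "
                "the model may be non-stabilizable"
            )
    return P


def subobserved_innovation_variance(model: VARModel, observed) -> np.ndarray:
    """Innovation covariance of the process restricted to ``observed``.

    Solves the DARE of the sub-observed state-space model — the full model
    with observation rows limited to ``observed`` — giving the one-step
    prediction-error covariance of those processes from their joint past
    only.  Returns a matrix aligned with the order of ``observed``.
    """
    observed = list(observed)
    if len(observed) == 0:
        raise ValueError("observed set must be non-empty")
    ss = var_to_ss(model)
    if sorted(observed) == list(range(model.n_processes)):
        return model.Sigma[np.ix_(observed, observed)]
    Cr = ss.C[observed, :]
    Q = ss.K @ ss.Sigma @ ss.K.T
    R = ss.Sigma[np.ix_(observed, observed)]
    S = ss.K @ ss.Sigma[:, observed]
    P = _solve_filter_dare(ss.F, Cr, Q, R, S)
    return Cr @ P @ Cr.T + R


def restricted_residual_variance(model: VARModel, target: int, excluded: int) -> float:
    """Innovation variance of X_target predicted from the past of every
    process except ``excluded`` (analytic, no refitting)."""
    if target == excluded:
        raise ValueError("target and excluded source must differ")
    observed = [q for q in range(model.n_processes) if q != excluded]
    V = subobserved_innovation_variance(model, observed)
    return float(V[observed.index(target), observed.index(target)])


def _half_log_ratio(s_r: float, s_u: float, base: str) -> float:
    if s_u <= 0:
        raise ValueError(f"degenerate innovation variance sigma2_u = {s_u}")
    if s_r < s_u - 1e-12:
        raise AssertionError(
            f"restricted variance {s_r} below unrestricted {s_u}: "
            "non-negativity of cTE violated"
        )
    val = 0.5 * np.log(max(s_r, s_u) / s_u)
    return float(val / np.log(2)) if base == "bits" else float(val)


def cte_pair(model: VARModel, i: int, j: int, units: str = "nats") -> float:
    """Conditional transfer entropy cTE(i -> j | S), S = all except i and j.

    Both the restricted and the unrestricted predictor keep the past of the
    target and of the N-2 conditioning processes; only the source's past is
    withheld in the restricted one.
    """
    if i == j:
        raise ValueError("source and target must differ")
    s_u = float(model.Sigma[j, j])
    s_r = restricted_residual_variance(model, target=j, excluded=i)
    return _half_log_ratio(s_r, s_u, units)


def bivariate_te(model: VARModel, i: int, j: int, units: str = "nats") -> float:
    """Unconditioned (pairwise) transfer entropy i -> j: predictor sets are
    {j} vs {i, j}, ignoring every other process.  Used as the contrast
    showing what multivariate conditioning removes (mediated influences)."""
    if i == j:
        raise ValueError("source and target must differ")
    V_uni = subobserved_innovation_variance(model, [j])
    V_biv = subobserved_innovation_variance(model, [i, j])
    s_r = float(V_uni[0, 0])
    s_u = float(V_biv[[i, j].index(j), [i, j].index(j)])
    return _half_log_ratio(s_r, s_u, units)


@dataclass
class CTEResult:
    """N x N conditional transfer entropy with the residual variances behind
    each entry.  matrix[i, j] = cTE(i -> j | S); diagonal fixed at zero."""

    matrix: np.ndarray
    node_out: np.ndarray
    sigma_u: np.ndarray  # sigma_u[i, j] = unrestricted innovation var of j
    sigma_r: np.ndarray  # sigma_r[i, j] = restricted var of j excluding i
    units: str = "nats"

    @property
    def n_processes(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (source, target, cte, sigma_u, sigma_r) table."""
        n = self.n_processes
        rows = [
            {
                "source": i,
                "target": j,
                "cte": self.matrix[i, j],
                "sigma_u": self.sigma_u[i, j],
                "sigma_r": self.sigma_r[i, j],
            }
            for i in range(n)
            for j in range(n)
            if i != j
        ]
        return pd.DataFrame(rows)

    def to_json(self, path=None) -> str:
        payload = {
            "matrix": self.matrix.tolist(),
            "node_out": self.node_out.tolist(),
            "sigma_u": self.sigma_u.tolist(),
            "sigma_r": self.sigma_r.tolist(),
            "units": self.units,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def cte_matrix(model: VARModel, units: str = "nats") -> CTEResult:
    """All-pairs conditional transfer entropy of a fitted VAR.

    One DARE solve per excluded source covers every target at once.
    """
    if units not in ("nats", "bits"):
        raise ValueError(f"unknown units {units!r}")
    n = model.n_processes
    mat = np.zeros((n, n))
    s_u = np.zeros((n, n))
    s_r = np.zeros((n, n))
    for i in range(n):
        observed = [q for q in range(n) if q != i]
        V = subobserved_innovation_variance(model, observed)
        for pos, j in enumerate(observed):
            su = float(model.Sigma[j, j])
            sr = float(V[pos, pos])
            s_u[i, j] = su
            s_r[i, j] = sr
            mat[i, j] = _half_log_ratio(sr, su, units)
    node = mat.sum(axis=1) / (n - 1)
    return CTEResult(matrix=mat, node_out=node, sigma_u=s_u, sigma_r=s_r, units=units)


def cte_node(result: CTEResult, i: int) -> float:
    """Node-level outflow: mean of row i over its N-1 targets."""
    n = result.n_processes
    row = np.delete(result.matrix[i], i)
    return float(row.sum() / (n - 1))


@dataclass
class BinaryAdjacency:
    """Binary directed adjacency: Mbin[i, j] True = significant link i -> j."""

    Mbin: np.ndarray
    rule: str

    def __post_init__(self):
        self.Mbin = np.asarray(self.Mbin, dtype=bool)
        if self.Mbin.ndim != 2 or self.Mbin.shape[0] != self.Mbin.shape[1]:
            raise ValueError("adjacency must be square")
        if np.diag(self.Mbin).any():
            raise ValueError("adjacency diagonal must be empty")

    @property
    def n_nodes(self) -> int:
        return self.Mbin.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.Mbin.sum())


def binarize(result: CTEResult, rule: str = "exact-zero") -> BinaryAdjacency:
    """Threshold the cTE matrix into a binary adjacency.

    ``"exact-zero"`` (default): a link is present iff its cTE exceeds 1e-10 —
    the LASSO's structural zeros make absent links exactly zero, so no
    further test is needed.  ``"quantile:Q"``: keep entries above the Q
    quantile of the off-diagonal values.
    """
    mat = result.matrix.copy()
    np.fill_diagonal(mat, 0.0)
    if rule == "exact-zero":
        adj = mat > LINK_THRESHOLD
    elif rule.startswith("quantile:"):
        q = float(rule.split(":", 1)[1])
        if not 0 <= q <= 1:
            raise ValueError(f"quantile must be in [0, 1], got {q}")
        off = mat[~np.eye(mat.shape[0], dtype=bool)]
        adj = mat > np.quantile(off, q)
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    np.fill_diagonal(adj, False)
    return BinaryAdjacency(Mbin=adj, rule=rule)
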