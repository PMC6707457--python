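"""Constrained factorization of allele-frequency estimates into P and Q.

Given an estimate ``F_hat`` of the individual-specific allele frequencies,
global ancestry estimation reduces to the nonconvex problem

    minimize ||F_hat - P Q||_F
    subject to  P in [0,1]^{m x d}           (box constraint)
                Q >= 0, columns sum to 1     (simplex constraint)

solved here by alternating least squares in two flavours:

* ``tals`` (truncated ALS): each block is solved *unconstrained* by
  minimum-norm least squares, then forced feasible — P is truncated into
  [0,1] entrywise and each column of Q is Euclidean-projected onto the
  probability simplex.  Fast; no monotonicity guarantee.
* ``cals`` (constrained ALS): each block is solved *exactly* under its
  constraint — per-column simplex-constrained least squares for Q and
  per-row box-constrained least squares for P.  Block-optimal updates make
  the objective non-increasing and every limit point a stationary point.

``fit_alstructure`` chains subspace estimation, projection and a chosen
ALS routine into the full pipeline.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .genotype_io import GenotypeMatrix
from .lse import FrequencyEstimate, LatentSubspace, estimate_subspace, project_frequencies

__all__ = [
    "AdmixtureFactors",
    "AdmixtureFit",
    "project_to_simplex",
    "truncate_unit_interval",
    "tals",
    "cals",
    "fit_alstructure",
]

_ENUM_MAX_D = 8  # active-set enumeration limit for the cALS subproblems


# ---------------------------------------------------------------------------
# feasibility primitives


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a vector onto the probability simplex.

    Computes ``argmin_w ||v - w||^2`` subject to ``w >= 0, sum(w) = 1`` by
    the sort-and-threshold method: with ``u`` the coordinates sorted in
    descending order, find the largest ``rho`` with
    ``u_rho - (sum_{i<=rho} u_i - 1)/rho > 0``, set
    ``tau = (sum_{i<=rho} u_i - 1)/rho`` and return ``max(v - tau, 0)``.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("project_to_simplex expects a non-empty 1-D vector")
    return project_columns_to_simplex(v[:, None])[:, 0]


def project_columns_to_simplex(V: np.ndarray) -> np.ndarray:
    """Column-wise simplex projection of a ``d x n`` matrix."""
    V = np.asarray(V, dtype=float)
    d, n = V.shape
    U = -np.sort(-V, axis=0)  # descending per column
    css = np.cumsum(U, axis=0)
    k = np.arange(1, d + 1)[:, None]
    cond = U - (css - 1.0) / k > 0
    # rho = last index where cond holds; cond always holds at k=1
    rho = d - 1 - np.argmax(cond[::-1], axis=0)
    tau = (css[rho, np.arange(n)] - 1.0) / (rho + 1.0)
    return np.maximum(V - tau, 0.0)


def truncate_unit_interval(M: np.ndarray) -> np.ndarray:
    """Entrywise truncation into [0, 1]."""
    return np.clip(M, 0.0, 1.0)


# ---------------------------------------------------------------------------
# exact constrained least-squares blocks (cALS)


def _simplex_ls_columns(P: np.ndarray, F: np.ndarray, Q_prev: np.ndarray | None) -> np.ndarray:
    """Solve ``min ||f - P q||`` with q on the simplex, for every column f of F.

    The problem per column is a d-variable QP; its optimum is the solution
    of the equality-constrained system restricted to its (unknown) support.
    For small d we enumerate all non-empty supports S, solve the shared KKT
    system once with all columns as right-hand sides, and keep the feasible
    candidate with the lowest objective.  ``Q_prev`` (if given) is kept as a
    further candidate so the block objective can never increase.
    """
    d, n = P.shape[1], F.shape[1]
    if d > _ENUM_MAX_D:
        return _simplex_ls_columns_generic(P, F)
    A = P.T @ P
    B = P.T @ F  # d x n
    best_obj = np.full(n, np.inf)
    best_Q = np.zeros((d, n))
    for r in range(1, d + 1):
        for S in itertools.combinations(range(d), r):
            S = list(S)
            M = np.zeros((r + 1, r + 1))
            M[:r, :r] = A[np.ix_(S, S)]
            M[:r, r] = 1.0
            M[r, :r] = 1.0
            rhs = np.vstack([B[S], np.ones((1, n))])
            try:
                sol = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
            qS = sol[:r]
            valid = np.all(qS >= -1e-10, axis=0)
            if not valid.any():
                continue
            obj = np.einsum("kj,kl,lj->j", qS, A[np.ix_(S, S)], qS) - 2.0 * np.sum(B[S] * qS, axis=0)
            better = valid & (obj < best_obj)
            if better.any():
                best_obj[better] = obj[better]
                cand = np.zeros((d, n))
                cand[S] = np.clip(qS, 0.0, None)
                best_Q[:, better] = cand[:, better]
    if Q_prev is not None:
        obj_prev = np.einsum("kj,kl,lj->j", Q_prev, A, Q_prev) - 2.0 * np.sum(B * Q_prev, axis=0)
        keep = obj_prev < best_obj - 1e-15
        if keep.any():
            best_Q[:, keep] = Q_prev[:, keep]
    # renormalize away accumulated round-off on the equality constraint
    best_Q /= best_Q.sum(axis=0, keepdims=True)
    return best_Q


def _simplex_ls_columns_generic(P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Per-column SLSQP fallback for d beyond the enumeration limit."""
    from scipy.optimize import minimize

    d, n = P.shape[1], F.shape[1]
    A = P.T @ P
    B = P.T @ F
    Q = np.empty((d, n))
    cons = [{"type": "eq", "fun": lambda q: q.sum() - 1.0, "jac": lambda q: np.ones_like(q)}]
    bounds = [(0.0, None)] * d
    x0 = np.full(d, 1.0 / d)
    for j in range(n):
        b = B[:, j]
        res = minimize(
            lambda q: q @ A @ q - 2.0 * b @ q,
            x0,
            jac=lambda q: 2.0 * (A @ q - b),
            bounds=bounds,
            constraints=cons,
            method="SLSQP",
        )
        Q[:, j] = project_to_simplex(res.x)
    return Q


def _box_ls_rows(Q: np.ndarray, F: np.ndarray, P_prev: np.ndarray | None) -> np.ndarray:
    """Solve ``min ||f - p Q||`` with p in [0,1]^d, for every row f of F.

    Enumerates active-set patterns (each coordinate free, pinned at 0, or
    pinned at 1); each pattern's stationary system is shared across rows,
    so one small solve handles all m right-hand sides.  ``P_prev`` is kept
    as a candidate for strict block descent.
    """
    d, m = Q.shape[0], F.shape[0]
    if d > _ENUM_MAX_D:
        return _box_ls_rows_generic(Q, F)
    B = Q @ Q.T
    C = Q @ F.T  # d x m
    best_obj = np.full(m, np.inf)
    best_P = np.zeros((m, d))
    for pattern in itertools.product((0, 1, 2), repeat=d):
        S = [k for k, s in enumerate(pattern) if s == 2]
        fixed = [k for k, s in enumerate(pattern) if s != 2]
        t = np.array([float(pattern[k]) for k in fixed])
        cand = np.zeros((d, m))
        if fixed:
            cand[fixed] = t[:, None]
        if S:
            rhs = C[S]
            if fixed:
                rhs = rhs - (B[np.ix_(S, fixed)] @ t)[:, None]
            try:
                pS = np.linalg.solve(B[np.ix_(S, S)], rhs)
            except np.linalg.LinAlgError:
                pS = np.linalg.lstsq(B[np.ix_(S, S)], rhs, rcond=None)[0]
            valid = np.all((pS >= -1e-10) & (pS <= 1.0 + 1e-10), axis=0)
            cand[S] = np.clip(pS, 0.0, 1.0)
        else:
            valid = np.ones(m, dtype=bool)
        if not valid.any():
            continue
        obj = np.einsum("km,kl,lm->m", cand, B, cand) - 2.0 * np.sum(C * cand, axis=0)
        better = valid & (obj < best_obj)
        if better.any():
            best_obj[better] = obj[better]
            best_P[better] = cand[:, better].T
    if P_prev is not None:
        Pp = P_prev.T
        obj_prev = np.einsum("km,kl,lm->m", Pp, B, Pp) - 2.0 * np.sum(C * Pp, axis=0)
        keep = obj_prev < best_obj - 1e-15
        if keep.any():
            best_P[keep] = P_prev[keep]
    return best_P


def _box_ls_rows_generic(Q: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Row-by-row bounded least squares fallback for large d."""
    from scipy.optimize import lsq_linear

    d, m = Q.shape[0], F.shape[0]
    P = np.empty((m, d))
    A = Q.T  # n x d
    for i in range(m):
        P[i] = lsq_linear(A, F[i], bounds=(0.0, 1.0)).x
    return P


# ---------------------------------------------------------------------------
# ALS drivers


@dataclass
class AdmixtureFactors:
    """Result of an ALS factorization of F_hat.

    ``P`` is ``m x d`` with entries in [0,1]; ``Q`` is ``d x n`` with
    non-negative columns summing to 1.  ``objective_trace`` records the
    Frobenius residual ``||F_hat - P Q||_F`` after every sweep.
    """

    P: np.ndarray
    Q: np.ndarray
    objective_trace: np.ndarray
    iterations: int
    converged: bool
    algorithm: str


def _as_fhat_values(Fhat: FrequencyEstimate | np.ndarray) -> np.ndarray:
    values = Fhat.values if isinstance(Fhat, FrequencyEstimate) else np.asarray(Fhat, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("F_hat contains non-finite entries")
    return values


def _objective(normF2: float, F: np.ndarray, P: np.ndarray, Q: np.ndarray) -> float:
    """||F - PQ||_F via the trace identity (avoids forming the m x n product)."""
    PtF = P.T @ F
    val = normF2 - 2.0 * np.sum(PtF * Q) + np.sum((P.T @ P) * (Q @ Q.T))
    return float(np.sqrt(max(val, 0.0)))


def _revive_dead_rows(Q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Re-initialize any all-zero row of Q (a population that lost all mass)."""
    dead = ~np.any(Q > 1e-12, axis=1)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} admixture component(s) collapsed to zero; re-initializing",
            stacklevel=3,
        )
        Q = Q.copy()
        Q[dead] = rng.uniform(0.0, 1.0, size=(int(dead.sum()), Q.shape[1]))
        Q = project_columns_to_simplex(Q)
    return Q


def _als_loop(
    Fhat: FrequencyEstimate | np.ndarray,
    d: int,
    tol: float,
    max_iter: int,
    seed: int | np.random.Generator,
    algorithm: Literal["tals", "cals"],
) -> AdmixtureFactors:
    F = _as_fhat_values(Fhat)
    m, n = F.shape
    if not 1 <= d <= min(m, n):
        raise ValueError(f"d must satisfy 1 <= d <= min(m, n) = {min(m, n)}, got {d}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    P = rng.uniform(0.0, 1.0, size=(m, d))
    Q = np.full((d, n), 1.0 / d)
    normF2 = float(np.sum(F * F))
    trace: list[float] = []
    converged = False
    iterations = 0

    for iterations in range(1, max_iter + 1):
        Q_old = Q
        if algorithm == "tals":
            # unconstrained minimum-norm LS, then force feasibility
            Q = np.linalg.pinv(P) @ F
            Q = project_columns_to_simplex(Q)
            Q = _revive_dead_rows(Q, rng)
            P = truncate_unit_interval(F @ np.linalg.pinv(Q))
        else:
            Q = _simplex_ls_columns(P, F, Q_old if iterations > 1 else None)
            Q = _revive_dead_rows(Q, rng)
            P = _box_ls_rows(Q, F, P if iterations > 1 else None)
        trace.append(_objective(normF2, F, P, Q))
        denom = max(float(np.linalg.norm(Q_old)), 1e-300)
        if float(np.linalg.norm(Q - Q_old)) / denom < tol:
            converged = True
            break

    return AdmixtureFactors(
        P=P,
        Q=Q,
        objective_trace=np.asarray(trace),
        iterations=iterations,
        converged=converged,
        algorithm=algorithm,
    )


def tals(
    Fhat: FrequencyEstimate | np.ndarray,
    d: int,
    tol: float = 1e-5,
    max_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AdmixtureFactors:
    """Truncated ALS: unconstrained block LS followed by feasibility repair.

    Each sweep solves the two unconstrained least-squares blocks by
    minimum-norm SVD solves, then projects Q's columns onto the simplex and
    truncates P into [0,1].  Stops when the relative Frobenius change of Q
    between sweeps drops below ``tol``.  The repair steps mean the
    objective is recorded but not guaranteed monotone.
    """
    return _als_loop(Fhat, d, tol, max_iter, seed, "tals")


def cals(
    Fhat: FrequencyEstimate | np.ndarray,
    d: int,
    tol: float = 1e-5,
    max_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AdmixtureFactors:
    """Constrained ALS: exact block-coordinate descent on the feasible set.

    The Q block solves a simplex-constrained least-squares QP per column
    and the P block a box-constrained QP per row, so the objective trace is
    non-increasing and limit points are stationary.  Slower than ``tals``
    but carries the descent guarantee.
    """
    return _als_loop(Fhat, d, tol, max_iter, seed, "cals")


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class AdmixtureFit:
    """Complete output of the pipeline: F_hat, P_hat, Q_hat plus diagnostics."""

    F: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    subspace: LatentSubspace
    clamped_fraction: float
    objective_trace: np.ndarray
    iterations: int
    converged: bool
    algorithm: str
    d: int
    tol: float
    max_iter: int
    seed: int | None
    sample_ids: Sequence[str] | None = None
    snp_ids: Sequence[str] | None = None
    eigenvalues: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.eigenvalues = self.subspace.eigenvalues


def fit_alstructure(
    X: GenotypeMatrix | np.ndarray,
    d: int,
    algorithm: Literal["tals", "cals"] = "tals",
    tol: float = 1e-5,
    max_iter: int = 1000,
    seed: int = 0,
) -> AdmixtureFit:
    """Fit the admixture model: subspace estimation, projection, factorization.

    The three stages are (i) estimate the latent row subspace of Q from the
    adjusted Gram matrix of X, (ii) project X/2 onto it to estimate the
    individual-specific allele frequencies, (iii) factor that estimate into
    P (ancestral frequencies) and Q (admixture proportions) with the chosen
    ALS routine.  ``tals`` is the default for speed; ``cals`` trades time
    for a monotone-descent guarantee.  Output components are ordered by
    decreasing variation explained ``||X q_k'||^2`` so row labels are
    deterministic; they remain arbitrary up to permutation in the model.
    """
    if algorithm not in ("tals", "cals"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    geno = X if isinstance(X, GenotypeMatrix) else GenotypeMatrix(np.asarray(X))
    subspace = estimate_subspace(geno, d)
    fhat = project_frequencies(geno, subspace, clamp="unit_interval")
    factors = _als_loop(fhat, d, tol, max_iter, seed, algorithm)

    # deterministic component order: decreasing variation explained
    s2 = np.zeros(d)
    for start in range(0, geno.m, 65536):
        block = geno.values[start : start + 65536].astype(np.float64)
        s2 += np.sum((block @ factors.Q.T) ** 2, axis=0)
    order = np.argsort(-s2, kind="stable")
    P = factors.P[:, order]
    Q = factors.Q[order]

    return AdmixtureFit(
        F=fhat.values,
        P=P,
        Q=Q,
        subspace=subspace,
        clamped_fraction=fhat.clamped_fraction,
        objective_trace=factors.objective_trace,
        iterations=factors.iterations,
        converged=factors.converged,
        algorithm=algorithm,
        d=d,
        tol=tol,
        max_iter=max_iter,
        seed=seed if isinstance(seed, int) else None,
        sample_ids=geno.sample_ids,
        snp_ids=geno.snp_ids,
    )
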