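"""Evaluation of admixture fits: aligned errors, likelihood, diagnostics.

The admixture factorization is identifiable at best up to a permutation of
the ancestral-population labels, so error metrics on Q are computed after
an optimal row alignment.  Alignment minimizes the RMSE over permutations;
because the objective separates over matched rows this is a linear
assignment problem, and for small d it coincides with exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import binom

from .genotype_io import GenotypeMatrix

__all__ = [
    "FitMetrics",
    "align_factors",
    "rmse",
    "mae",
    "mean_loglik",
    "variation_explained",
    "check_anchor_individuals",
    "check_anchor_snps",
    "evaluate_fit",
]

LOGLIK_EPS = 1e-8  # frequency bound keeping binomial log terms finite


@dataclass
class FitMetrics:
    """Permutation-aligned error metrics for an estimated Q (and optional F)."""

    rmse: float
    mae: float
    alignment: np.ndarray
    mean_loglik: float | None = None
    variation_explained: np.ndarray | None = None


def align_factors(Qhat: np.ndarray, Qtrue: np.ndarray) -> np.ndarray:
    """Row permutation ``perm`` of Qhat minimizing RMSE against Qtrue.

    Returns ``perm`` such that ``Qhat[perm]`` is the aligned estimate.
    Solved as a linear assignment on the pairwise squared-error cost
    ``C[k, l] = ||Qhat_k - Qtrue_l||^2``; the RMSE objective separates over
    matched rows, so this equals brute-force search over permutations.
    """
    Qhat = np.asarray(Qhat, dtype=float)
    Qtrue = np.asarray(Qtrue, dtype=float)
    if Qhat.shape != Qtrue.shape:
        raise ValueError(f"shape mismatch: {Qhat.shape} vs {Qtrue.shape}")
    d = Qhat.shape[0]
    cost = np.empty((d, d))
    for k in range(d):
        cost[k] = np.sum((Qhat[k][None, :] - Qtrue) ** 2, axis=1)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(d, dtype=int)
    perm[cols] = rows
    return perm


def rmse(Qhat: np.ndarray, Qtrue: np.ndarray, aligned: bool = True) -> float:
    """Root mean squared error ``sqrt((1/(dn)) sum (qhat - q)^2)``.

    With ``aligned=True`` (default) the optimal row permutation is applied
    first; without alignment the metric is confounded by label switching.
    """
    Qhat = np.asarray(Qhat, dtype=float)
    Qtrue = np.asarray(Qtrue, dtype=float)
    if Qhat.shape != Qtrue.shape:
        raise ValueError(f"shape mismatch: {Qhat.shape} vs {Qtrue.shape}")
    if aligned:
        Qhat = Qhat[align_factors(Qhat, Qtrue)]
    return float(np.sqrt(np.mean((Qhat - Qtrue) ** 2)))


def mae(Qhat: np.ndarray, Qtrue: np.ndarray, aligned: bool = True) -> float:
    """Mean absolute error ``(1/(dn)) sum |qhat - q|``, aligned by default."""
    Qhat = np.asarray(Qhat, dtype=float)
    Qtrue = np.asarray(Qtrue, dtype=float)
    if Qhat.shape != Qtrue.shape:
        raise ValueError(f"shape mismatch: {Qhat.shape} vs {Qtrue.shape}")
    if aligned:
        Qhat = Qhat[align_factors(Qhat, Qtrue)]
    return float(np.mean(np.abs(Qhat - Qtrue)))


def mean_loglik(X: GenotypeMatrix | np.ndarray, Fhat: np.ndarray) -> float:
    """Mean per-observation binomial log-likelihood of the data under F_hat.

    ``(1/(mn)) sum log P(x_ij | 2, f_ij)`` with the binomial coefficient
    included (a constant log 2 for heterozygotes).  Frequencies are bounded
    into ``[eps, 1-eps]`` (eps = 1e-8) so boundary estimates stay finite;
    entries outside [0, 1] before bounding are an error.
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    Fhat = np.asarray(Fhat, dtype=float)
    if Fhat.shape != values.shape:
        raise ValueError(f"shape mismatch: X {values.shape} vs F_hat {Fhat.shape}")
    if np.any((Fhat < 0.0) | (Fhat > 1.0)):
        raise ValueError("F_hat has entries outside [0, 1]; clamp before evaluating")
    bounded = np.clip(Fhat, LOGLIK_EPS, 1.0 - LOGLIK_EPS)
    return float(np.mean(binom.logpmf(values, 2, bounded)))


def variation_explained(X: GenotypeMatrix | np.ndarray, Qhat: np.ndarray) -> np.ndarray:
    """Per-component variation explained ``s_k^2 = ||X q_k'||^2``.

    Used to order output components deterministically (descending s^2).
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    Qhat = np.asarray(Qhat, dtype=float)
    if Qhat.shape[1] != values.shape[1]:
        raise ValueError("Qhat column count does not match X")
    s2 = np.zeros(Qhat.shape[0])
    for start in range(0, values.shape[0], 65536):
        block = values[start : start + 65536].astype(np.float64)
        s2 += np.sum((block @ Qhat.T) ** 2, axis=0)
    return s2


def check_anchor_individuals(Q: np.ndarray, tol: float = 0.05) -> tuple[bool, dict[int, int]]:
    """Check whether every population has a near-unadmixed individual.

    Population k is anchored when some column j has ``q_kj >= 1 - tol``:
    individual j's genome comes (nearly) entirely from population k.  A
    full set of d anchors makes the factorization identifiable up to
    permutation.  Returns the verdict and one witness column per anchored
    population.
    """
    Q = np.asarray(Q, dtype=float)
    witnesses: dict[int, int] = {}
    for k in range(Q.shape[0]):
        j = int(np.argmax(Q[k]))
        if Q[k, j] >= 1.0 - tol:
            witnesses[k] = j
    return len(witnesses) == Q.shape[0], witnesses


def check_anchor_snps(P: np.ndarray, tol: float = 0.05) -> tuple[bool, dict[int, int]]:
    """Check whether every population has a SNP fixed in all others.

    SNP i anchors population k when its frequency is within ``tol`` of 0 or
    1 in every population except k, and interior in k.  Symmetric in the
    two fixation directions.
    """
    P = np.asarray(P, dtype=float)
    m, d = P.shape
    near_fixed = np.minimum(P, 1.0 - P) <= tol
    witnesses: dict[int, int] = {}
    for k in range(d):
        others = np.delete(np.arange(d), k)
        mask = np.all(near_fixed[:, others], axis=1) & ~near_fixed[:, k]
        if mask.any():
            witnesses[k] = int(np.argmax(mask))
    return len(witnesses) == d, witnesses


def evaluate_fit(
    Qhat: np.ndarray,
    Qtrue: np.ndarray,
    X: GenotypeMatrix | np.ndarray | None = None,
    Fhat: np.ndarray | None = None,
) -> FitMetrics:
    """Aligned RMSE/MAE, plus likelihood and variation explained when data given."""
    perm = align_factors(Qhat, Qtrue)
    aligned = np.asarray(Qhat, dtype=float)[perm]
    out = FitMetrics(
        rmse=rmse(aligned, Qtrue, aligned=False),
        mae=mae(aligned, Qtrue, aligned=False),
        alignment=perm,
    )
    if X is not None and Fhat is not None:
        out.mean_loglik = mean_loglik(X, Fhat)
    if X is not None:
        out.variation_explained = variation_explained(X, aligned)
    return out
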