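"""Latent subspace estimation and projection-based allele-frequency estimates.

Under the admixture model, genotypes satisfy ``x_ij ~ Binomial(2, f_ij)``
with ``F = PQ`` of rank ``d``.  The row space of ``Q`` (equivalently of
``F``) can be estimated consistently from the data alone: the top ``d``
eigenvectors of the heteroscedasticity-adjusted Gram matrix

    ``G = (1/m) X'X - D``,    ``D = diag(delta_1, ..., delta_n)``,

span the latent subspace as ``m`` grows, where ``delta_j`` is the average
heterozygosity of column ``j`` and corrects the column-wise binomial noise
variance that plain PCA would absorb.  Projecting the rows of ``X/2`` onto
the estimated subspace then yields an (asymptotically) unbiased estimate of
the individual-specific allele frequencies ``F``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg

from .genotype_io import GenotypeMatrix

__all__ = [
    "LatentSubspace",
    "FrequencyEstimate",
    "hetero_adjustment",
    "adjusted_gram",
    "estimate_subspace",
    "project_frequencies",
]

# row-block size for accumulating X'X without materializing X as float64
_BLOCK_ROWS = 65536


@dataclass
class LatentSubspace:
    """Estimated d-dimensional row subspace of the admixture matrix Q.

    Attributes
    ----------
    basis
        ``n x d`` matrix whose columns are orthonormal eigenvectors of G,
        sign-fixed so each column's largest-magnitude entry is positive.
    eigenvalues
        All ``n`` eigenvalues of G in descending order.  The trailing
        ``n - d`` of them converge to zero as m grows; they are kept for
        scree diagnostics.
    d
        Latent dimension (number of ancestral populations).
    hetero_adjust
        The length-n heterozygosity vector delta used to build D.
    """

    basis: np.ndarray
    eigenvalues: np.ndarray
    d: int
    hetero_adjust: np.ndarray

    def __post_init__(self) -> None:
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.d), atol=1e-10):
            raise ValueError("subspace basis is not orthonormal")


@dataclass
class FrequencyEstimate:
    """Individual-specific allele-frequency estimates F-hat (``m x n``).

    ``clamped_fraction`` records the proportion of entries moved by
    clamping into [0, 1]; pre-clamp rows lie in the span of the subspace
    basis, so the matrix has numerical rank at most d.
    """

    values: np.ndarray
    clamped_fraction: float
    d: int


def hetero_adjustment(X: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-individual average heterozygosity ``delta_j = (1/m) sum_i (2x - x^2)``.

    For genotypes in {0,1,2} the summand is the heterozygosity indicator
    (``2x - x^2`` equals 1 iff x = 1, else 0), so ``delta_j`` is exactly the
    fraction of heterozygous sites in column j.  It estimates the binomial
    noise variance ``(2/m) sum_i f_ij (1 - f_ij)`` that inflates the
    diagonal of the naive Gram matrix.
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    m = values.shape[0]
    # delta_j = heterozygote fraction; integer count avoids float accumulation
    return np.count_nonzero(values == 1, axis=0) / m


def adjusted_gram(X: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Heteroscedasticity-adjusted Gram matrix ``G = (1/m) X'X - D``.

    Accumulated over row blocks in float64 (X is stored as int8) and
    symmetrized exactly before returning.
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    m, n = values.shape
    gram = np.zeros((n, n))
    for start in range(0, m, _BLOCK_ROWS):
        block = values[start : start + _BLOCK_ROWS].astype(np.float64)
        gram += block.T @ block
    gram /= m
    gram[np.diag_indices(n)] -= hetero_adjustment(values)
    return (gram + gram.T) / 2.0


def estimate_subspace(X: GenotypeMatrix | np.ndarray, d: int) -> LatentSubspace:
    """Estimate the latent row subspace of Q from the top-d eigenvectors of G.

    Parameters
    ----------
    X
        Validated genotype matrix.
    d
        Latent dimension, ``1 <= d <= n``.  Choosing d is outside this
        package's scope (a structural Hardy-Weinberg test is the usual
        route); it is taken as user input.
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    n = values.shape[1]
    if not 1 <= d <= n:
        raise ValueError(f"d must satisfy 1 <= d <= n = {n}, got {d}")
    G = adjusted_gram(values)
    eigvals, eigvecs = scipy.linalg.eigh(G)  # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    scale = np.abs(eigvals[0])
    if n > d and scale > 0 and (eigvals[d - 1] - eigvals[d]) < 1e-6 * scale:
        warnings.warn(
            f"eigenvalue gap between components {d} and {d + 1} is below "
            f"1e-6 of the leading eigenvalue; the rank-{d} subspace is "
            "ill-determined",
            stacklevel=2,
        )

    basis = eigvecs[:, :d].copy()
    _fix_signs(basis)
    return LatentSubspace(basis=basis, eigenvalues=eigvals, d=d, hetero_adjust=hetero_adjustment(values))


def _fix_signs(basis: np.ndarray) -> None:
    """Flip each column so its largest-magnitude entry is positive.

    Ties on magnitude break toward the earliest index, making the output
    reproducible across linear-algebra backends.
    """
    for k in range(basis.shape[1]):
        col = basis[:, k]
        idx = np.argmax(np.abs(col))  # argmax returns the first maximal index
        if col[idx] < 0:
            basis[:, k] = -col


def project_frequencies(
    X: GenotypeMatrix | np.ndarray,
    subspace: LatentSubspace,
    clamp: Literal["none", "unit_interval"] = "unit_interval",
) -> FrequencyEstimate:
    """Project genotype rows onto the subspace: ``F_hat = (1/2) X V V'``.

    With ``clamp="unit_interval"`` (the pipeline default) entries are
    truncated into [0, 1] — the projection can overshoot slightly — and the
    altered fraction recorded.  ``clamp="none"`` preserves the raw
    projection, whose rows lie exactly in the span of the basis (rank <= d).
    """
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X)
    V = subspace.basis
    if V.shape[0] != values.shape[1]:
        raise ValueError(
            f"subspace basis has {V.shape[0]} rows but X has {values.shape[1]} columns"
        )
    m = values.shape[0]
    fhat = np.empty(values.shape, dtype=np.float64)
    for start in range(0, m, _BLOCK_ROWS):
        block = values[start : start + _BLOCK_ROWS].astype(np.float64)
        fhat[start : start + _BLOCK_ROWS] = 0.5 * ((block @ V) @ V.T)
    clamped_fraction = 0.0
    if clamp == "unit_interval":
        out_of_range = np.count_nonzero((fhat < 0.0) | (fhat > 1.0))
        clamped_fraction = out_of_range / fhat.size
        np.clip(fhat, 0.0, 1.0, out=fhat)
    elif clamp != "none":
        raise ValueError(f"unknown clamp mode {clamp!r}")
    return FrequencyEstimate(values=fhat, clamped_fraction=clamped_fraction, d=subspace.d)
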