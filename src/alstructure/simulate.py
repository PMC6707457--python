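"""Genotype simulators with ground truth under the admixture model.

Two generative designs are provided:

* the classic PSD design — columns of Q drawn Dirichlet(alpha), entries of
  P drawn from the Balding-Nichols distribution, a Beta reparameterized by
  a per-SNP F_ST and ancestral allele frequency;
* a spatial diffusion design — d ancestral populations diffuse on a line
  from unit-spaced origins, and an individual sampled at position x has
  admixture proportions given by normalized Gaussian density weights.
  Its Q columns lie on a one-dimensional curve inside the d-dimensional
  simplex, a deliberately hard regime for subspace-based estimation.

In both, genotypes are drawn ``x_ij ~ Binomial(2, f_ij)`` with ``F = PQ``,
site by site independently (no linkage disequilibrium).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .genotype_io import GenotypeMatrix

__all__ = [
    "PSDParams",
    "SpatialParams",
    "SimulationTruth",
    "sample_balding_nichols",
    "alpha_prototype",
    "default_bn_params",
    "simulate_psd",
    "simulate_spatial",
]

_BLOCK_ROWS = 65536
_EDGE_EPS = 1e-12  # keep Balding-Nichols draws strictly interior


@dataclass
class PSDParams:
    """Parameters of the PSD design (Dirichlet admixture, Balding-Nichols P).

    ``bn_fst`` and ``bn_maf`` are per-SNP vectors of F_ST and ancestral
    allele frequency; if omitted they are drawn from the documented proxy
    distribution (see :func:`default_bn_params`).
    """

    m: int
    n: int
    d: int
    alpha: np.ndarray
    bn_fst: np.ndarray | None = None
    bn_maf: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.m < 1 or self.n < 1 or self.d < 1:
            raise ValueError("m, n, d must all be positive")
        if self.alpha.shape != (self.d,):
            raise ValueError(f"alpha must have length d={self.d}")
        if np.any(self.alpha <= 0):
            raise ValueError("alpha entries must be positive")
        for name in ("bn_fst", "bn_maf"):
            vec = getattr(self, name)
            if vec is not None:
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (self.m,):
                    raise ValueError(f"{name} must have length m={self.m}")
                if np.any((vec <= 0) | (vec >= 1)):
                    raise ValueError(f"{name} entries must lie strictly in (0, 1)")
                setattr(self, name, vec)


@dataclass
class SpatialParams:
    """Parameters of the spatial diffusion design.

    Population k has origin ``mu_k = x0 + k`` (unit spacing) and diffusion
    standard deviation ``sigma``.  Sampling ``positions`` default to a
    uniform grid spanning ``[mu_1 - 2 sigma, mu_d + 2 sigma]``; a uniform
    random placement over the same interval is also available.
    """

    m: int
    n: int
    d: int
    sigma: float
    x0: float = 0.0
    positions: np.ndarray | None = None
    position_rule: Literal["grid", "uniform"] = "grid"
    bn_fst: np.ndarray | None = None
    bn_maf: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.d < 2:
            raise ValueError("the spatial design needs d >= 2 populations")
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (self.n,):
                raise ValueError(f"positions must have length n={self.n}")

    @property
    def means(self) -> np.ndarray:
        return self.x0 + np.arange(self.d, dtype=float)


@dataclass
class SimulationTruth:
    """A simulated dataset together with its generating parameters.

    ``F`` is derived as ``P @ Q`` on access rather than stored, since at
    typical sizes (10^5 x 10^3) it dwarfs everything else.
    """

    P: np.ndarray
    Q: np.ndarray
    X: GenotypeMatrix
    params: PSDParams | SpatialParams

    @property
    def F(self) -> np.ndarray:
        return self.P @ self.Q


def sample_balding_nichols(
    fst: float | np.ndarray,
    p: float | np.ndarray,
    count: int | tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw allele frequencies from Balding-Nichols(F, p).

    This is the Beta distribution reparameterized by F_ST and the ancestral
    frequency: ``Beta(((1-F)/F) p, ((1-F)/F)(1-p))``, with mean ``p`` and
    variance ``F p (1-p)``.  Draws numerically equal to 0 or 1 are nudged
    into the open interval so downstream binomial likelihoods stay finite.
    """
    fst = np.asarray(fst, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((fst <= 0) | (fst >= 1)):
        raise ValueError("fst must lie strictly in (0, 1)")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    scale = (1.0 - fst) / fst
    draws = rng.beta(scale * p, scale * (1.0 - p), size=count)
    return np.clip(draws, _EDGE_EPS, 1.0 - _EDGE_EPS)


def alpha_prototype(name: Literal["a1", "a2", "a3", "a4"], d: int) -> np.ndarray:
    """Standard Dirichlet concentration prototypes for d populations.

    ``a1`` = (10,...,10): columns near the simplex center; ``a2`` =
    (1,...,1): uniform over the simplex; ``a3`` = (0.1,...,0.1): columns on
    edges/vertices (anchor-like individuals); ``a4`` mixes all three scales
    in equal blocks — (10,1,0.1) at d=3, (10,10,1,1,0.1,0.1) at d=6 —
    and therefore requires d divisible by 3.
    """
    if d < 1:
        raise ValueError("d must be positive")
    if name == "a1":
        return np.full(d, 10.0)
    if name == "a2":
        return np.full(d, 1.0)
    if name == "a3":
        return np.full(d, 0.1)
    if name == "a4":
        if d % 3 != 0:
            raise ValueError("the a4 prototype requires d divisible by 3")
        return np.repeat([10.0, 1.0, 0.1], d // 3)
    raise ValueError(f"unknown alpha prototype {name!r}")


def default_bn_params(m: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Proxy per-SNP Balding-Nichols parameters.

    Draws ``p_i ~ Uniform(0.1, 0.9)`` and ``F_i ~ Uniform(0.01, 0.2)`` —
    ranges typical of common human SNPs — as a synthetic stand-in for
    parameter vectors estimated from a reference panel.  Supply your own
    ``bn_fst``/``bn_maf`` vectors to use real estimates.
    """
    if m < 1:
        raise ValueError("m must be positive")
    bn_fst = rng.uniform(0.01, 0.2, size=m)
    bn_maf = rng.uniform(0.1, 0.9, size=m)
    return bn_fst, bn_maf


def _draw_p_and_genotypes(
    Q: np.ndarray,
    bn_fst: np.ndarray,
    bn_maf: np.ndarray,
    d: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw P row-blocks and genotypes X ~ Binomial(2, PQ) without holding F."""
    m = bn_fst.shape[0]
    n = Q.shape[1]
    P = np.empty((m, d))
    X = np.empty((m, n), dtype=np.int8)
    for start in range(0, m, _BLOCK_ROWS):
        stop = min(start + _BLOCK_ROWS, m)
        sl = slice(start, stop)
        P[sl] = sample_balding_nichols(
            bn_fst[sl, None], bn_maf[sl, None], (stop - start, d), rng
        )
        F_block = P[sl] @ Q
        X[sl] = rng.binomial(2, F_block).astype(np.int8)
    return P, X


def simulate_psd(params: PSDParams) -> SimulationTruth:
    """Simulate from the PSD design.

    Columns of Q are i.i.d. Dirichlet(alpha); row i of P holds d i.i.d.
    Balding-Nichols(F_i, p_i) draws; genotypes are Binomial(2, PQ).  Fully
    reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    bn_fst, bn_maf = params.bn_fst, params.bn_maf
    if bn_fst is None or bn_maf is None:
        proxy_fst, proxy_maf = default_bn_params(params.m, rng)
        bn_fst = proxy_fst if bn_fst is None else bn_fst
        bn_maf = proxy_maf if bn_maf is None else bn_maf
    Q = rng.dirichlet(params.alpha, size=params.n).T  # d x n
    P, X = _draw_p_and_genotypes(Q, bn_fst, bn_maf, params.d, rng)
    return SimulationTruth(P=P, Q=Q, X=GenotypeMatrix(X), params=params)


def spatial_admixture(positions: np.ndarray, means: np.ndarray, sigma: float) -> np.ndarray:
    """Admixture proportions at sampling positions under the diffusion model.

    ``q_k(x)`` is the Gaussian density of population k at x, normalized
    over populations: ``phi((x - mu_k)/sigma) / sum_l phi((x - mu_l)/sigma)``.
    Translation-invariant in (positions, means) jointly.  Computed on the
    log scale for stability far from all population centers.
    """
    positions = np.asarray(positions, dtype=float)
    z = -0.5 * ((positions[None, :] - means[:, None]) / sigma) ** 2  # d x n
    z -= z.max(axis=0, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=0, keepdims=True)


def simulate_spatial(params: SpatialParams) -> SimulationTruth:
    """Simulate from the spatial diffusion design.

    Q's columns follow the normalized-Gaussian weight curve at the sampling
    positions; P and X are generated exactly as in :func:`simulate_psd`.
    """
    rng = np.random.default_rng(params.seed)
    means = params.means
    lo, hi = means[0] - 2.0 * params.sigma, means[-1] + 2.0 * params.sigma
    positions = params.positions
    if positions is None:
        if params.position_rule == "grid":
            positions = np.linspace(lo, hi, params.n)
        elif params.position_rule == "uniform":
            positions = np.sort(rng.uniform(lo, hi, size=params.n))
        else:
            raise ValueError(f"unknown position_rule {params.position_rule!r}")
    Q = spatial_admixture(positions, means, params.sigma)
    bn_fst, bn_maf = params.bn_fst, params.bn_maf
    if bn_fst is None or bn_maf is None:
        proxy_fst, proxy_maf = default_bn_params(params.m, rng)
        bn_fst = proxy_fst if bn_fst is None else bn_fst
        bn_maf = proxy_maf if bn_maf is None else bn_maf
    P, X = _draw_p_and_genotypes(Q, bn_fst, bn_maf, params.d, rng)
    out_params = SpatialParams(
        m=params.m,
        n=params.n,
        d=params.d,
        sigma=params.sigma,
        x0=params.x0,
        positions=positions,
        position_rule=params.position_rule,
        bn_fst=params.bn_fst,
        bn_maf=params.bn_maf,
        seed=params.seed,
    )
    return SimulationTruth(P=P, Q=Q, X=GenotypeMatrix(X), params=out_params)
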