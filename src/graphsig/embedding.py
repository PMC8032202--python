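"""Diffusion-maps embedding of signature vectors.

A second, global graph is built over the n per-point signatures with a
Gaussian kernel on the (squared) l1 distance,

    W2(k, l) = exp(-||pi_k - pi_l||_1^2 / (2 eps')),

the random walk P2 = D^{-1} W2 is eigendecomposed through its symmetric
conjugate, and the data points are mapped to the leading non-trivial right
eigenvectors scaled by powers of their eigenvalues.  Euclidean distances in
that map approximate the diffusion distance of the walk.  The number of
informative coordinates is chosen by comparing the observed spectrum with
the spectra of row-permuted null kernels (a Jackstraw-style permutation
test adapted to diffusion maps).

The l1 metric is the default because the total variation between two SSDs
(which are probability vectors) is exactly an l1 distance; l2 is offered
for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .signatures import DegenerateScaleError

__all__ = [
    "SignatureMatrix",
    "GlobalGraphModel",
    "EmbeddingResult",
    "JackstrawConfig",
    "build_global_graph",
    "diffusion_maps",
    "diffusion_distance",
    "jackstraw_dimension",
    "embed_pipeline",
]


@dataclass
class SignatureMatrix:
    """n signature vectors stacked row-wise, with optional point/group labels."""

    rows: np.ndarray
    point_ids: Sequence[str] | None = None
    group_ids: Sequence[str] | None = None
    kind: str | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[0] < 2:
            raise ValueError("rows must be an (n >= 2) x m matrix")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("signature matrix has non-finite entries")
        if self.kind == "SSD" and not np.allclose(self.rows.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("SSD rows must each sum to 1")
        for name in ("point_ids", "group_ids"):
            labels = getattr(self, name)
            if labels is not None and len(labels) != self.rows.shape[0]:
                raise ValueError(f"{name} length does not match n")

    @property
    def n_points(self) -> int:
        return self.rows.shape[0]


@dataclass
class GlobalGraphModel:
    """Kernel graph over signatures and its random walk."""

    weights: np.ndarray
    transition: np.ndarray
    epsilon_prime: float
    metric: str = "l1"
    squared: bool = True
    signature_rows: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class EmbeddingResult:
    """Spectral embedding of the global graph.

    ``coordinates`` column k-1 holds lam_{k}^t phi_k for k = 2..l+1; the
    constant first eigenvector is dropped.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    dimension: int
    coordinates: np.ndarray
    diffusion_time: int
    epsilon_prime: float | None = None
    point_ids: Sequence[str] | None = None
    group_ids: Sequence[str] | None = None
    jackstraw: "JackstrawConfig | None" = None


@dataclass
class JackstrawConfig:
    """Permutation-null settings for the dimension test.

    ``permutation_scope`` selects the null: ``"columns"`` (default)
    independently permutes each signature coordinate across points and
    rebuilds the kernel -- the classic Jackstraw device, which preserves
    per-coordinate marginals while destroying the joint geometry;
    ``"kernel-rows"`` permutes entries within each row of the kernel
    matrix itself and re-symmetrizes.
    """

    shuffles: int = 100
    seed: int = 0
    permutation_scope: str = "columns"

    def __post_init__(self) -> None:
        if self.shuffles < 1:
            raise ValueError("shuffles must be >= 1")
        if self.permutation_scope not in ("columns", "kernel-rows"):
            raise ValueError("permutation_scope must be 'columns' or 'kernel-rows'")


def build_global_graph(
    sigs: SignatureMatrix,
    epsilon_prime: float | str = "median",
    metric: str = "l1",
    squared: bool = True,
) -> GlobalGraphModel:
    """Gaussian kernel over pairwise l1 (default) or l2 signature distances.

    With ``squared=True`` (the default) the squared distance sits in the
    exponent numerator; ``epsilon_prime="median"`` resolves to the median of
    the pairwise quantities used in that numerator.
    """
    if metric not in ("l1", "l2"):
        raise ValueError("metric must be 'l1' or 'l2'")
    dist = pdist(sigs.rows, metric="cityblock" if metric == "l1" else "euclidean")
    numer = dist**2 if squared else dist
    if isinstance(epsilon_prime, str):
        if epsilon_prime != "median":
            raise ValueError("epsilon_prime must be a positive scalar or 'median'")
        eps = float(np.median(numer))
        if eps <= 0:
            raise DegenerateScaleError(
                "all signatures identical; median pairwise distance is zero -- "
                "pass epsilon_prime explicitly"
            )
    else:
        eps = float(epsilon_prime)
        if not np.isfinite(eps) or eps <= 0:
            raise ValueError("epsilon_prime must be positive")
    weights = squareform(np.exp(-numer / (2.0 * eps)))
    np.fill_diagonal(weights, 1.0)
    transition = weights / weights.sum(axis=1)[:, None]
    return GlobalGraphModel(weights=weights, transition=transition,
                            epsilon_prime=eps, metric=metric, squared=squared,
                            signature_rows=sigs.rows.copy())


def _spectral(graph: GlobalGraphModel):
    """Eigenpairs of P2, scaled so phi_1 = 1 and nu_1 is the stationary law.

    Returns (lam, phi, nu): descending eigenvalues, right eigenvectors with
    the constant first column, and biorthogonal left eigenvectors whose
    first column sums to 1.
    """
    deg = graph.degrees
    inv_sqrt = 1.0 / np.sqrt(deg)
    sym = graph.weights * np.outer(inv_sqrt, inv_sqrt)
    lam, v = np.linalg.eigh(sym)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    v = v[:, order]
    flips = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flips[flips == 0] = 1.0
    v = v * flips
    total = deg.sum()
    phi = v * inv_sqrt[:, None] * np.sqrt(total)
    nu = v * np.sqrt(deg)[:, None] / np.sqrt(total)
    return lam, phi, nu


def diffusion_maps(graph: GlobalGraphModel, t: int = 1, l: int = 1,
                   sigs: SignatureMatrix | None = None,
                   jackstraw: JackstrawConfig | None = None) -> EmbeddingResult:
    """Map each point to (lam_2^t phi_2, ..., lam_{l+1}^t phi_{l+1})."""
    n = graph.n_nodes
    if not 0 <= l <= n - 1:
        raise ValueError(f"l must be in [0, n-1], got {l}")
    if t < 1 or not float(t).is_integer():
        raise ValueError("t must be a positive integer")
    lam, phi, _ = _spectral(graph)
    coords = phi[:, 1 : l + 1] * (lam[1 : l + 1] ** int(t))
    return EmbeddingResult(
        eigenvalues=lam,
        eigenvectors=phi,
        dimension=l,
        coordinates=coords,
        diffusion_time=int(t),
        epsilon_prime=graph.epsilon_prime,
        point_ids=None if sigs is None else sigs.point_ids,
        group_ids=None if sigs is None else sigs.group_ids,
        jackstraw=jackstraw,
    )


def diffusion_distance(graph: GlobalGraphModel, t: int, i: int, j: int) -> float:
    """Diffusion distance D_t(i, j) from the rows of P^t.

    D_t^2(i, j) = sum_k (P^t(i,k) - P^t(j,k))^2 / nu_1(k), with nu_1 the
    stationary distribution of the walk.
    """
    P_t = np.linalg.matrix_power(graph.transition, int(t))
    deg = graph.degrees
    nu1 = deg / deg.sum()
    diff = P_t[i] - P_t[j]
    return float(np.sqrt(np.sum(diff**2 / nu1)))


def _permuted_rows(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each signature coordinate across points."""
    permuted = np.empty_like(rows)
    for j in range(rows.shape[1]):
        permuted[:, j] = rows[rng.permutation(rows.shape[0]), j]
    return permuted


def _spectrum_of_kernel(weights: np.ndarray) -> np.ndarray:
    np.fill_diagonal(weights, 1.0)
    deg = weights.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    lam = np.linalg.eigvalsh(weights * np.outer(inv_sqrt, inv_sqrt))
    return np.sort(np.abs(lam))[::-1]


def _null_spectrum(graph: GlobalGraphModel, rng: np.random.Generator,
                   scope: str) -> np.ndarray:
    """|eigenvalues| of one permutation null, descending.

    ``columns`` rebuilds the kernel (at the observed scale) from
    column-permuted signatures -- the classic Jackstraw device, preserving
    per-coordinate marginals while destroying the joint geometry.
    ``kernel-rows`` permutes entries within each row of the observed
    kernel and re-symmetrizes by averaging with the transpose.  Both
    nulls restore the unit diagonal and row-normalize, so they remain
    valid row-stochastic matrices.
    """
    if scope == "columns":
        if graph.signature_rows is None:
            raise ValueError("column permutation requires the signature rows")
        rows = _permuted_rows(graph.signature_rows, rng)
        dist = pdist(rows, metric="cityblock" if graph.metric == "l1"
                     else "euclidean")
        numer = dist**2 if graph.squared else dist
        weights = squareform(np.exp(-numer / (2.0 * graph.epsilon_prime)))
    else:
        n = graph.n_nodes
        weights = np.empty_like(graph.weights)
        for i in range(n):
            weights[i] = graph.weights[i, rng.permutation(n)]
        weights = 0.5 * (weights + weights.T)
    return _spectrum_of_kernel(weights)


def jackstraw_dimension(graph: GlobalGraphModel,
                        config: JackstrawConfig | None = None) -> int:
    """Number of informative embedding coordinates by a permutation null.

    The observed eigenvalues (descending) are compared index-by-index with
    the maximum over ``shuffles`` null spectra.  Scanning from the second
    eigenvalue upward, dimensions pass while lam(x) >= max_k |lam*_k(x)|
    (ties pass); the count of consecutive passes is returned, excluding the
    trivial first eigenvector.
    """
    config = config or JackstrawConfig()
    rng = np.random.default_rng(config.seed)
    lam, _, _ = _spectral(graph)
    nulls = np.vstack([_null_spectrum(graph, rng, config.permutation_scope)
                       for _ in range(config.shuffles)])
    null_max = nulls.max(axis=0)
    l = 0
    for x in range(1, graph.n_nodes):  # 0-based index x = dimension x+1
        if lam[x] >= null_max[x] - 1e-12:  # ties pass (up to roundoff)
            l += 1
        else:
            break
    return l


def embed_pipeline(
    sigs: SignatureMatrix,
    epsilon_prime: float | str = "median",
    t: int = 1,
    jackstraw: JackstrawConfig | None = None,
    metric: str = "l1",
    dimension: int | None = None,
) -> EmbeddingResult:
    """Signature matrix -> global graph -> dimension choice -> embedding.

    ``dimension`` overrides the permutation test when given.
    """
    graph = build_global_graph(sigs, epsilon_prime=epsilon_prime, metric=metric)
    if dimension is None:
        jackstraw = jackstraw or JackstrawConfig()
        l = jackstraw_dimension(graph, jackstraw)
        l = min(l, graph.n_nodes - 1)
    else:
        l = dimension
    return diffusion_maps(graph, t=t, l=l, sigs=sigs, jackstraw=jackstraw)
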