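"""Per-data-point graph signatures.

One data point x_i is observed through m feature vectors f_1(x_i), ...,
f_m(x_i), each of length d.  A complete weighted graph over the m features
is built with a Gaussian kernel on pairwise Euclidean distances,

    W(k, l) = exp(-||f_k - f_l||^2 / (2 eps)),

and a random walk on it has transition matrix P = D^{-1} W.  Because W is
symmetric with unit diagonal, the walk is irreducible and aperiodic and its
unique stationary distribution -- the steady-state distribution (SSD) -- is
the normalized degree vector.  The SSD is the primary signature; the
spectral comparators DKS, HKS and WKS are low-/band-pass filters of the
same transition operator's spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ObservationBundle",
    "LocalGraphModel",
    "SpectralDecomposition",
    "SignatureVector",
    "build_local_graph",
    "default_epsilon",
    "ssd",
    "spectral_decompose",
    "dks",
    "hks",
    "wks",
    "multiscale_ssd",
]

_ROW_SUM_TOL = 1e-10
_RECONSTRUCTION_TOL = 1e-8


class DegenerateScaleError(ValueError):
    """All pairwise distances are zero; no data-driven kernel scale exists."""


@dataclass
class ObservationBundle:
    """The m feature vectors (rows) of one data point, each of length d."""

    features: np.ndarray
    feature_names: Sequence[str] | None = None
    point_id: str | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (m x d) array")
        m, d = self.features.shape
        if m < 2:
            raise ValueError(f"need at least 2 features, got m={m}")
        if d < 1:
            raise ValueError("feature vectors must have length >= 1")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if self.feature_names is not None and len(self.feature_names) != m:
            raise ValueError("feature_names length does not match m")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def patch_dim(self) -> int:
        return self.features.shape[1]


@dataclass
class LocalGraphModel:
    """Gaussian-kernel graph over one bundle's features and its random walk."""

    weights: np.ndarray
    degrees: np.ndarray
    transition: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        row_sums = self.transition.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=_ROW_SUM_TOL):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class SpectralDecomposition:
    """Eigenpairs of the local transition operator.

    ``right_vectors`` (psi) and ``left_vectors`` (phi) are scaled so that
    ``sum_j lam_j^t psi_j phi_j^T`` reconstructs P^t; ``sym_vectors`` are the
    orthonormal eigenvectors of D^{-1/2} W D^{-1/2}.
    """

    eigenvalues: np.ndarray
    right_vectors: np.ndarray
    left_vectors: np.ndarray
    sym_vectors: np.ndarray

    def reconstruct(self, t: int = 1) -> np.ndarray:
        lam_t = self.eigenvalues**t
        return (self.right_vectors * lam_t) @ self.left_vectors.T


@dataclass
class SignatureVector:
    """A per-feature signature of one data point."""

    values: np.ndarray
    kind: str
    scale: float
    time: float | None = None
    sigma: float | None = None
    point_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signature has non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("signature entries must be nonnegative")
        if self.kind == "SSD":
            total = self.values.sum()
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"SSD must sum to 1 (got {total})")


def build_local_graph(bundle: ObservationBundle, epsilon: float) -> LocalGraphModel:
    """Gaussian-kernel graph W(k,l) = exp(-||f_k - f_l||^2 / (2 epsilon))."""
    if not np.isfinite(epsilon) or epsilon <= 0:
        raise ValueError(f"epsilon must be a positive finite scalar, got {epsilon}")
    sq = squareform(pdist(bundle.features, metric="sqeuclidean"))
    weights = np.exp(-sq / (2.0 * epsilon))
    np.fill_diagonal(weights, 1.0)
    degrees = weights.sum(axis=1)
    transition = weights / degrees[:, None]
    return LocalGraphModel(weights=weights, degrees=degrees, transition=transition,
                           epsilon=float(epsilon))


def default_epsilon(bundle: ObservationBundle) -> float:
    """Median of the pairwise *squared* Euclidean distances among features.

    Squared distances are used because epsilon sits under the squared norm
    in the kernel exponent, so it is a squared-distance scale.
    """
    sq = pdist(bundle.features, metric="sqeuclidean")
    med = float(np.median(sq))
    if med <= 0.0:
        raise DegenerateScaleError(
            "all features are identical; the median pairwise distance is zero -- "
            "pass epsilon explicitly"
        )
    return med


def ssd(graph: LocalGraphModel) -> SignatureVector:
    """Steady-state distribution of the random walk: normalized degrees.

    The stationary distribution of P = D^{-1} W with symmetric W is
    proportional to the degree vector, so no eigendecomposition is needed.
    """
    values = graph.degrees / graph.degrees.sum()
    return SignatureVector(values=values, kind="SSD", scale=graph.epsilon)


def spectral_decompose(graph: LocalGraphModel) -> SpectralDecomposition:
    """Eigenpairs of P via the symmetrized operator D^{-1/2} W D^{-1/2}.

    The symmetric route guarantees a real spectrum; right/left eigenvectors
    of P follow by the degree rescaling psi = D^{-1/2} v, phi = D^{1/2} v.
    """
    dec = _decompose(graph.weights, graph.degrees)
    P = graph.transition
    for t in (1, 2):
        err = np.max(np.abs(dec.reconstruct(t) - np.linalg.matrix_power(P, t)))
        if err > _RECONSTRUCTION_TOL:
            raise ArithmeticError(
                f"spectral reconstruction of P^{t} failed (max error {err:.2e})"
            )
    return dec


def _decompose(weights: np.ndarray, degrees: np.ndarray) -> SpectralDecomposition:
    inv_sqrt = 1.0 / np.sqrt(degrees)
    sym = weights * np.outer(inv_sqrt, inv_sqrt)
    lam, v = np.linalg.eigh(sym)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    v = v[:, order]
    # deterministic sign: largest-magnitude entry of each eigenvector positive
    flips = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flips[flips == 0] = 1.0
    v = v * flips
    psi = v * inv_sqrt[:, None]
    phi = v * np.sqrt(degrees)[:, None]
    return SpectralDecomposition(eigenvalues=lam, right_vectors=psi,
                                 left_vectors=phi, sym_vectors=v)


def _eigen_power(lam: np.ndarray, t: float) -> np.ndarray:
    """lam**t, sign-safe: exact for integer t, negatives clamped otherwise."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    if float(t).is_integer():
        return np.sign(lam) ** int(t) * np.abs(lam) ** int(t)
    return np.where(lam < 0, 0.0, lam) ** t


def dks(graph: LocalGraphModel, t: float) -> SignatureVector:
    """Diffusion kernel signature: DKS_t(k) = sum_j lam_j^t psi_j(k)^2."""
    dec = spectral_decompose(graph)
    values = (dec.right_vectors**2) @ _eigen_power(dec.eigenvalues, t)
    return SignatureVector(values=values, kind="DKS", scale=graph.epsilon, time=t)


def hks(graph: LocalGraphModel, t: float) -> SignatureVector:
    """Heat kernel signature: HKS_t(k) = sum_j exp(-(1-lam_j) t) psi_j(k)^2."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    dec = spectral_decompose(graph)
    weights_j = np.exp(-(1.0 - dec.eigenvalues) * t)
    values = (dec.right_vectors**2) @ weights_j
    return SignatureVector(values=values, kind="HKS", scale=graph.epsilon, time=t)


def wks(graph: LocalGraphModel, t: float, sigma: float | None = None) -> SignatureVector:
    """Wave kernel signature: a log-Gaussian band-pass over the spectrum.

    Band j is centered at log(1 - lam_j); eigenvalues with 1 - lam_j <= 1e-12
    (the stationary component) have no finite log-energy and are excluded.
    The band weights are normalized to sum to one.  The default bandwidth is
    one seventh of the log-spectral range.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if sigma is not None and sigma <= 0:
        raise ValueError("sigma must be positive")
    dec = spectral_decompose(graph)
    included = (1.0 - dec.eigenvalues) > 1e-12
    if not np.any(included):
        raise ValueError("no eigenvalues with 1 - lambda > 0; WKS undefined")
    log_e = np.log(1.0 - dec.eigenvalues[included])
    if sigma is None:
        span = float(log_e.max() - log_e.min())
        sigma = span / 7.0 if span > 0 else 1.0
    band = np.exp(-((np.log(t) - log_e) ** 2) / (2.0 * sigma**2))
    band /= band.sum()
    values = (dec.right_vectors[:, included] ** 2) @ band
    return SignatureVector(values=values, kind="WKS", scale=graph.epsilon,
                           time=t, sigma=float(sigma))


def multiscale_ssd(bundle: ObservationBundle, epsilons: Sequence[float]) -> np.ndarray:
    """Stack of SSDs at several kernel scales, one row per epsilon."""
    epsilons = list(epsilons)
    if not epsilons:
        raise ValueError("epsilons must be nonempty")
    rows = [ssd(build_local_graph(bundle, eps)).values for eps in epsilons]
    return np.vstack(rows)
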