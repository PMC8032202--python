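"""End-to-end convenience: bundles -> signatures -> embedding.

Mirrors the two-stage procedure: per-bundle signatures (stage 1) stacked
into a matrix, then the l1-kernel diffusion embedding (stage 2).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .signatures import (
    ObservationBundle,
    build_local_graph,
    default_epsilon,
    ssd,
    dks,
    hks,
    wks,
    multiscale_ssd,
)
from .embedding import (
    SignatureMatrix,
    EmbeddingResult,
    JackstrawConfig,
    embed_pipeline,
)

__all__ = ["pooled_median_epsilon", "compute_signatures", "graph_of_graphs"]


def pooled_median_epsilon(bundles: Sequence[ObservationBundle]) -> float:
    """Median squared pairwise feature distance pooled over all bundles.

    A single shared kernel scale keeps the stage-1 signatures of different
    data points comparable.
    """
    dists = np.concatenate([pdist(b.features, metric="sqeuclidean")
                            for b in bundles])
    med = float(np.median(dists))
    if med <= 0:
        raise ValueError("pooled median distance is zero; pass epsilon explicitly")
    return med


def compute_signatures(
    bundles: Sequence[ObservationBundle],
    kind: str = "ssd",
    epsilon: float | Sequence[float] | str = "median",
    t: float = 1.0,
    sigma: float | None = None,
    group_ids: Sequence[str] | None = None,
) -> SignatureMatrix:
    """Stage 1: one signature row per bundle.

    ``epsilon`` may be a scalar (shared scale), a list (multiscale SSD,
    rows concatenated per scale), or ``"median"`` for the pooled median of
    squared pairwise distances across all bundles.
    """
    kind = kind.lower()
    if kind not in ("ssd", "dks", "hks", "wks"):
        raise ValueError("kind must be one of ssd, dks, hks, wks")
    multiscale = isinstance(epsilon, (list, tuple, np.ndarray))
    if multiscale and kind != "ssd":
        raise ValueError("multiscale signatures are defined for the SSD only")
    if isinstance(epsilon, str):
        if epsilon != "median":
            raise ValueError("epsilon must be a scalar, a list, or 'median'")
        epsilon = pooled_median_epsilon(bundles)
    rows = []
    for bundle in bundles:
        if multiscale:
            rows.append(multiscale_ssd(bundle, list(epsilon)).ravel())
            continue
        graph = build_local_graph(bundle, float(epsilon))
        if kind == "ssd":
            sig = ssd(graph)
        elif kind == "dks":
            sig = dks(graph, t)
        elif kind == "hks":
            sig = hks(graph, t)
        else:
            sig = wks(graph, t, sigma)
        rows.append(sig.values)
    return SignatureMatrix(
        rows=np.vstack(rows),
        point_ids=[b.point_id or str(i) for i, b in enumerate(bundles)],
        group_ids=group_ids,
        kind=("SSD-MULTISCALE" if multiscale
              else "SSD" if kind == "ssd" else kind.upper()),
    )


def graph_of_graphs(
    bundles: Sequence[ObservationBundle],
    kind: str = "ssd",
    epsilon: float | Sequence[float] | str = "median",
    epsilon_prime: float | str = "median",
    t: int = 1,
    jackstraw: JackstrawConfig | None = None,
    dimension: int | None = None,
    group_ids: Sequence[str] | None = None,
) -> EmbeddingResult:
    """Both stages: signatures then the diffusion-maps embedding."""
    sigs = compute_signatures(bundles, kind=kind, epsilon=epsilon,
                              group_ids=group_ids)
    return embed_pipeline(sigs, epsilon_prime=epsilon_prime, t=t,
                          jackstraw=jackstraw, dimension=dimension)
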