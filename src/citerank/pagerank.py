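"""PageRank over a citation graph.

The score of node :math:`p_i` satisfies the recurrence

.. math::

    PR(p_i) = \\frac{1-d}{N} + d \\sum_{p_j \\in M(p_i)} \\frac{PR(p_j)}{L(p_j)}

where :math:`d` is the dampening factor (probability the random surfer
follows a citation rather than teleporting), :math:`N` the number of unique
PMIDs, :math:`M(p_i)` the set of articles citing :math:`p_i` and
:math:`L(p_j)` the out-degree of :math:`p_j`. Iteration starts from the
uniform vector :math:`1/N` and stops when the L1 change between successive
iterates drops below epsilon.

Dangling nodes — in a citation corpus, typically PMIDs that were cited but
whose article was never parsed — have no outbound citations to follow; their
rank mass is redistributed uniformly over all nodes at each iteration, which
keeps the score vector a probability distribution (sum 1) and preserves the
random-surfer reading of the recurrence.

A dense linear-solve oracle (:func:`pagerank_oracle`) computes the same
stationary distribution exactly on small graphs and exists to cross-check
the power iteration in tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy import sparse

from .errors import EmptyGraphError, GraphSizeError
from .graph import CitationGraph, InvertedIndex

logger = logging.getLogger(__name__)

ORACLE_MAX_NODES = 200


@dataclass(frozen=True)
class PageRankParams:
    """Iteration parameters: dampening factor d, tolerance epsilon, cap."""

    d: float = 0.85
    epsilon: float = 1e-5
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ValueError(f"dampening factor must lie in (0, 1), got {self.d}")
        if self.epsilon <= 0.0:
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class PageRankVector:
    """Scores per PMID plus convergence metadata.

    ``scores`` sums to 1; every entry is at least ``(1-d)/N``. ``residual``
    is the final L1 change between iterates; ``residuals`` the full history.
    """

    scores: dict[int, float]
    iterations: int
    converged: bool
    residual: float
    params: PageRankParams
    residuals: tuple[float, ...] = field(default=(), repr=False)

    def __getitem__(self, pmid: int) -> float:
        return self.scores[pmid]


def _link_matrix(graph: CitationGraph) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Column-stochastic link matrix A (A[i,j] = 1/L(j) for edge j->i) and dangling mask."""
    n = graph.n_nodes
    index = graph.node_index
    rows = np.empty(graph.n_edges, dtype=np.int64)
    cols = np.empty(graph.n_edges, dtype=np.int64)
    for k, (u, v) in enumerate(graph.edges):
        cols[k] = index[u]
        rows[k] = index[v]
    out_deg = np.zeros(n, dtype=np.float64)
    np.add.at(out_deg, cols, 1.0)
    dangling = out_deg == 0.0
    vals = 1.0 / out_deg[cols]
    matrix = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return matrix, dangling


def compute_pagerank(graph: CitationGraph, params: PageRankParams | None = None) -> PageRankVector:
    """Power-iterate the PageRank recurrence to convergence.

    Raises :class:`EmptyGraphError` on an empty graph. If the L1 residual has
    not fallen below epsilon within ``max_iterations``, the last iterate is
    returned with ``converged=False`` and a warning is emitted.
    """
    if params is None:
        params = PageRankParams()
    n = graph.n_nodes
    if n == 0:
        raise EmptyGraphError("PageRank is undefined on an empty graph")
    matrix, dangling = _link_matrix(graph)
    d = params.d
    rank = np.full(n, 1.0 / n)
    residuals: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        dangling_mass = rank[dangling].sum()
        new_rank = (1.0 - d) / n + d * (matrix @ rank + dangling_mass / n)
        residual = float(np.abs(new_rank - rank).sum())
        residuals.append(residual)
        rank = new_rank
        if residual < params.epsilon:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"PageRank did not converge in {params.max_iterations} iterations "
            f"(final L1 residual {residuals[-1]:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    logger.info(
        "pagerank: N=%d edges=%d d=%g eps=%g iterations=%d converged=%s",
        n, graph.n_edges, d, params.epsilon, iterations, converged,
    )
    return PageRankVector(
        scores={pmid: float(score) for pmid, score in zip(graph.nodes, rank)},
        iterations=iterations,
        converged=converged,
        residual=residuals[-1],
        params=params,
        residuals=tuple(residuals),
    )


def pagerank_oracle(graph: CitationGraph, d: float = 0.85) -> PageRankVector:
    """Exact stationary scores by a dense linear solve; test oracle only.

    Solves ``(I - d*M) x = (1-d)/N`` where M is the column-stochastic
    transition matrix with dangling columns replaced by the uniform column
    ``1/N`` — the same operator the power iteration applies — so the solution
    is the iteration's fixed point and sums to 1. Refuses graphs larger than
    ``ORACLE_MAX_NODES`` nodes.
    """
    n = graph.n_nodes
    if n == 0:
        raise EmptyGraphError("PageRank is undefined on an empty graph")
    if n > ORACLE_MAX_NODES:
        raise GraphSizeError(
            f"oracle refuses graphs with more than {ORACLE_MAX_NODES} nodes (got {n})"
        )
    matrix, dangling = _link_matrix(graph)
    dense = matrix.toarray()
    dense[:, dangling] = 1.0 / n
    x = np.linalg.solve(np.eye(n) - d * dense, np.full(n, (1.0 - d) / n))
    x = x / x.sum()
    return PageRankVector(
        scores={pmid: float(score) for pmid, score in zip(graph.nodes, x)},
        iterations=0,
        converged=True,
        residual=0.0,
        params=PageRankParams(d=d),
    )


def write_scores(vector: PageRankVector, index: InvertedIndex, path: Union[str, Path]) -> None:
    """Write ``pmid<TAB>pagerank<TAB>citation_count``.

    PageRank printed with 6 significant digits in scientific notation;
    rows sorted by descending PageRank then ascending PMID.
    """
    counts = index.citation_count
    rows = sorted(vector.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for pmid, score in rows:
            handle.write(f"{pmid}\t{score:.6e}\t{counts.get(pmid, 0)}\n")


def read_scores(path: Union[str, Path]) -> tuple[dict[int, float], dict[int, int]]:
    """Read a score TSV back into (scores, citation_counts) maps."""
    scores: dict[int, float] = {}
    counts: dict[int, int] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            pmid_s, score_s, count_s = line.rstrip("\n").split("\t")
            pmid = int(pmid_s)
            scores[pmid] = float(score_s)
            counts[pmid] = int(count_s)
    return scores, counts
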