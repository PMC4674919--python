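"""Validation statistics: does PageRank track citation count?

PageRank is validated as a surrogate of literature importance by correlating
it against the conventional metric, citation count (in-degree), over a
random sample of graph nodes: a seeded uniform sample without replacement,
Pearson correlation with a two-sided significance test, and an ordinary
least-squares fit of PageRank on citation count. The sample size needed for
such a survey of a finite population is computed with the standard
finite-population proportion formula. A top-N table puts the two metrics
side by side for the highest-ranked articles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .errors import ConstantInputError, InsufficientDataError
from .graph import InvertedIndex
from .pagerank import PageRankVector


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation and simple-regression summary of a paired sample.

    ``direction`` records which variable was regressed on which;
    ``r_squared`` equals ``pearson_r ** 2`` (simple-regression identity).
    """

    n: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_correlation: float
    p_regression: float
    direction: str = "pagerank ~ citation_count"
    seed: int | None = None
    fraction: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        lines = [
            f"n           = {self.n}",
            f"Pearson R   = {self.pearson_r:.6f}  (p = {self.p_correlation:.3g})",
            f"R^2         = {self.r_squared:.6f}",
            f"fit         = {self.direction}: slope {self.slope:.6g}, "
            f"intercept {self.intercept:.6g}  (p = {self.p_regression:.3g})",
        ]
        if self.fraction is not None:
            lines.append(f"fraction    = {self.fraction}")
        if self.seed is not None:
            lines.append(f"seed        = {self.seed}")
        return "\n".join(lines)


@dataclass(frozen=True)
class RankTable:
    """Rows of (rank, pmid, pagerank, citation_count), descending PageRank."""

    rows: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self) -> None:
        ranks = [r for r, *_ in self.rows]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be contiguous 1..n")
        scores = [s for _, _, s, _ in self.rows]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("pagerank must be non-increasing down the table")

    def to_tsv(self) -> str:
        out = ["rank\tpmid\tpagerank\tcitation_count"]
        for rank, pmid, score, count in self.rows:
            out.append(f"{rank}\t{pmid}\t{score:.6e}\t{count}")
        return "\n".join(out) + "\n"


def _count_map(index: InvertedIndex | dict[int, int]) -> dict[int, int]:
    return index.citation_count if isinstance(index, InvertedIndex) else index


def sample_nodes(
    scores: dict[int, float] | PageRankVector,
    index: InvertedIndex | dict[int, int],
    fraction: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform sample of nodes; returns aligned (pagerank, count) arrays.

    Draws ``ceil(fraction * N)`` nodes without replacement from the node set
    in ascending-PMID order, so the same seed always yields the same sample.
    ``fraction=1.0`` returns the whole population in ascending-PMID order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    score_map = scores.scores if isinstance(scores, PageRankVector) else scores
    pmids = np.array(sorted(score_map), dtype=np.int64)
    n_pop = len(pmids)
    k = math.ceil(fraction * n_pop)
    if k < n_pop:
        rng = np.random.default_rng(seed)
        chosen = pmids[np.sort(rng.choice(n_pop, size=k, replace=False))]
    else:
        chosen = pmids
    counts = _count_map(index)
    pr = np.array([score_map[p] for p in chosen], dtype=np.float64)
    cc = np.array([counts.get(int(p), 0) for p in chosen], dtype=np.float64)
    return pr, cc


def required_sample_size(
    population: int,
    confidence: float = 0.95,
    margin: float = 0.05,
    response_distribution: float = 0.5,
) -> int:
    """Finite-population sample size for estimating a proportion.

    Returns ``ceil(N*x / ((N-1)*E^2 + x))`` with ``x = Z^2 * p * (1-p)``,
    where Z is the two-sided normal quantile for the confidence level, E the
    margin of error and p the assumed response distribution (0.5 is the
    conservative worst case).
    """
    if population < 1:
        raise ValueError("population must be >= 1")
    if not 0.0 < margin < 1.0:
        raise ValueError("margin must lie in (0, 1)")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    if not 0.0 < response_distribution < 1.0:
        raise ValueError("response_distribution must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
    x = z * z * response_distribution * (1.0 - response_distribution)
    n = population * x / ((population - 1) * margin * margin + x)
    return math.ceil(n)


def correlate(
    pagerank: np.ndarray,
    citation_count: np.ndarray,
    seed: int | None = None,
    fraction: float | None = None,
) -> CorrelationReport:
    """Pearson correlation plus OLS of PageRank on citation count.

    Raises :class:`InsufficientDataError` for n < 3 and
    :class:`ConstantInputError` when either variable is constant.
    """
    pagerank = np.asarray(pagerank, dtype=np.float64)
    citation_count = np.asarray(citation_count, dtype=np.float64)
    if pagerank.shape != citation_count.shape:
        raise ValueError("paired sample arrays must have equal length")
    n = len(pagerank)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    if np.ptp(pagerank) == 0.0 or np.ptp(citation_count) == 0.0:
        raise ConstantInputError("correlation undefined for a constant variable")
    pearson = stats.pearsonr(citation_count, pagerank)
    fit = stats.linregress(citation_count, pagerank)
    return CorrelationReport(
        n=n,
        pearson_r=float(pearson.statistic),
        r_squared=float(pearson.statistic) ** 2,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_correlation=float(pearson.pvalue),
        p_regression=float(fit.pvalue),
        seed=seed,
        fraction=fraction,
    )


def top_n(
    scores: dict[int, float] | PageRankVector,
    index: InvertedIndex | dict[int, int],
    n: int = 10,
) -> RankTable:
    """Top-n nodes by descending PageRank, ties broken by ascending PMID."""
    if n < 1:
        raise ValueError("n must be >= 1")
    score_map = scores.scores if isinstance(scores, PageRankVector) else scores
    if n > len(score_map):
        import warnings

        warnings.warn(
            f"requested top {n} of only {len(score_map)} nodes; table truncated",
            UserWarning,
            stacklevel=2,
        )
        n = len(score_map)
    counts = _count_map(index)
    ordered = sorted(score_map.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    rows = tuple(
        (rank, pmid, score, counts.get(pmid, 0))
        for rank, (pmid, score) in enumerate(ordered, start=1)
    )
    return RankTable(rows=rows)
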