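"""Directed citation graph over unique PMIDs, and its inverted index.

The node set is the union of all parsed article PMIDs and all cited PMIDs:
an article that is cited but never parsed still becomes a genuine node (a
"cited-only" node, dangling by construction, with out-degree 0). Nodes are
kept in ascending-PMID order so every derived output is reproducible.

The inverted index is the transpose view of the graph: for each node the
set of articles citing it, whose size is the conventional citation count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Union

from .errors import DuplicateArticleError, EdgeListFormatError
from .jats import ArticleRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CitationGraph:
    """Immutable directed graph of citations between PMIDs.

    Attributes
    ----------
    nodes
        All unique PMIDs, ascending.
    edges
        Distinct ``(citing, cited)`` pairs, sorted, with self-loops excluded.
    sources
        PMIDs that appeared as parsed articles (as opposed to cited-only).
    """

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    sources: frozenset[int]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate nodes")
        if list(self.nodes) != sorted(self.nodes):
            raise ValueError("nodes must be in ascending order")
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop edge {u}->{v}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in nodes: ({u}, {v})")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        if not self.sources <= node_set:
            raise ValueError("sources must be a subset of nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def node_index(self) -> dict[int, int]:
        """PMID -> position in ``nodes`` (ascending order)."""
        return {pmid: i for i, pmid in enumerate(self.nodes)}

    @cached_property
    def out_degree(self) -> dict[int, int]:
        """Number of outbound citations per node; 0 for cited-only nodes."""
        deg = dict.fromkeys(self.nodes, 0)
        for u, _ in self.edges:
            deg[u] += 1
        return deg

    def is_source(self, pmid: int) -> bool:
        """True iff the node appeared as a parsed article."""
        return pmid in self.sources


@dataclass(frozen=True)
class InvertedIndex:
    """Per-node inbound citation lists and citation counts."""

    inbound: dict[int, tuple[int, ...]]

    @cached_property
    def citation_count(self) -> dict[int, int]:
        return {pmid: len(citing) for pmid, citing in self.inbound.items()}

    @property
    def total_citations(self) -> int:
        return sum(self.citation_count.values())


def build_graph(records: Iterable[ArticleRecord]) -> CitationGraph:
    """Construct the citation graph from a stream of article records.

    Nodes are all article PMIDs plus all cited PMIDs; cited-but-absent PMIDs
    become cited-only nodes. Two records sharing a PMID raise
    :class:`DuplicateArticleError` rather than merging silently.
    """
    sources: set[int] = set()
    edges: set[tuple[int, int]] = set()
    nodes: set[int] = set()
    for record in records:
        if record.pmid in sources:
            raise DuplicateArticleError(record.pmid)
        sources.add(record.pmid)
        nodes.add(record.pmid)
        for cited in record.outbound:
            nodes.add(cited)
            edges.add((record.pmid, cited))
    return CitationGraph(
        nodes=tuple(sorted(nodes)),
        edges=tuple(sorted(edges)),
        sources=frozenset(sources),
    )


def build_inverted_index(graph: CitationGraph) -> InvertedIndex:
    """Inbound citation list for every node; count 0 permitted."""
    inbound: dict[int, list[int]] = {pmid: [] for pmid in graph.nodes}
    for u, v in graph.edges:
        inbound[v].append(u)
    return InvertedIndex(inbound={pmid: tuple(sorted(citing)) for pmid, citing in inbound.items()})


def from_edges(edges: Iterable[tuple[int, int]], sources: Iterable[int] | None = None) -> CitationGraph:
    """Build a graph from raw (citing, cited) pairs.

    Deduplicates and drops self-loops (logged). When ``sources`` is not
    given, every citing PMID is treated as a source article.
    """
    clean: set[tuple[int, int]] = set()
    dropped = 0
    for u, v in edges:
        if u == v:
            dropped += 1
            continue
        clean.add((u, v))
    if dropped:
        logger.info("dropped %d self-loop edge(s)", dropped)
    nodes = {u for u, _ in clean} | {v for _, v in clean}
    if sources is None:
        src = frozenset(u for u, _ in clean)
    else:
        src = frozenset(sources)
        nodes |= src
    return CitationGraph(nodes=tuple(sorted(nodes)), edges=tuple(sorted(clean)), sources=src)


def read_edge_list(path: Union[str, Path]) -> CitationGraph:
    """Read a two-column ``citing<TAB>cited`` TSV into a graph.

    The reader deduplicates and drops self-loops with a logged count;
    malformed lines raise :class:`EdgeListFormatError` with the line number.
    """
    path = Path(path)
    edges: list[tuple[int, int]] = []
    with open(path, encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not all(f.isdigit() for f in fields):
                raise EdgeListFormatError(str(path), line_number, line)
            edges.append((int(fields[0]), int(fields[1])))
    return from_edges(edges)


def write_edge_list(graph: CitationGraph, path: Union[str, Path]) -> None:
    """Write the canonical edge list: sorted pairs, one per line, LF, UTF-8."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for u, v in graph.edges:
            handle.write(f"{u}\t{v}\n")


def write_node_manifest(graph: CitationGraph, path: Union[str, Path]) -> None:
    """Write the PMIDs seen as citing source articles, ascending."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for pmid in sorted(graph.sources):
            handle.write(f"{pmid}\n")


def write_citation_counts(index: InvertedIndex, path: Union[str, Path]) -> None:
    """Write ``pmid<TAB>count``, sorted by descending count then ascending PMID."""
    rows = sorted(index.citation_count.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for pmid, count in rows:
            handle.write(f"{pmid}\t{count}\n")
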