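"""Synthetic citation corpora with the statistical shape of the real thing.

Real citation networks are grown, not sampled: articles appear over time,
cite only earlier work, and accumulate citations by cumulative advantage —
well-cited articles attract further citations — producing the heavy-tailed
citation-count distributions every bibliometric corpus shows. The generator
here is a Price-style preferential-attachment model: article t draws a
Poisson number of references and cites earlier articles with probability
proportional to (current in-degree + attachment_offset), each target cited
at most once per article. A configurable fraction of references creates a
fresh out-of-corpus PMID, emulating citations into literature outside the
parsed corpus; out-of-corpus nodes stay citable under the same attachment
kernel, so heavily cited classics outside the corpus accumulate large
citation counts exactly as dangling nodes do in a real citation network.
Duplicate and self references can be injected to exercise the parser's
cleanup rules.

Corpus-article PMIDs are drawn from a low range and out-of-corpus PMIDs
from a disjoint high range so provenance is auditable in any output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union
from xml.sax.saxutils import escape

import numpy as np

from .graph import CitationGraph, build_graph
from .jats import ArticleRecord

ARTICLE_PMID_BASE = 100_000
EXTERNAL_PMID_BASE = 900_000_000


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the Price-model corpus generator.

    n_articles
        Number of in-corpus (source) articles.
    mean_refs
        Expected reference-list length (Poisson mean).
    attachment_offset
        Additive constant a in the attachment kernel (in-degree + a); small
        a relative to the mean in-degree gives heavier tails.
    external_fraction
        Probability a reference points at a fresh out-of-corpus PMID.
    dup_rate, self_rate
        Per-article probabilities of injecting a duplicate reference or a
        self-citation into the raw reference list.
    seed
        RNG seed; identical params + seed reproduce the corpus exactly.
    """

    n_articles: int = 1000
    mean_refs: float = 8.0
    attachment_offset: float = 1.0
    external_fraction: float = 0.10
    dup_rate: float = 0.0
    self_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        if self.mean_refs < 0:
            raise ValueError("mean_refs must be >= 0")
        if self.attachment_offset < 0:
            raise ValueError("attachment_offset must be >= 0")
        for name in ("external_fraction", "dup_rate", "self_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


def generate_articles(params: GrowthParams) -> list[tuple[int, list[int]]]:
    """Raw per-article reference lists, including any injected dirt.

    Returns ``(pmid, references)`` pairs in publication order. Reference
    lists may contain injected duplicates and self-citations (per
    ``dup_rate``/``self_rate``); graph construction resolves them by the
    same rules the XML parser applies.
    """
    rng = np.random.default_rng(params.seed)
    a = params.attachment_offset
    external = params.external_fraction
    nodes: list[int] = []  # every citable PMID, in creation order
    cite_events: list[int] = []  # one entry per citation received
    next_external = EXTERNAL_PMID_BASE
    articles: list[tuple[int, list[int]]] = []
    for t in range(params.n_articles):
        pmid = ARTICLE_PMID_BASE + t
        k = int(rng.poisson(params.mean_refs))
        refs: list[int] = []
        chosen: set[int] = set()
        for _ in range(k):
            target: int | None = None
            if external > 0.0 and rng.random() < external:
                target = next_external
                next_external += 1
                nodes.append(target)
            else:
                # kernel (in-degree + a): pick a past citation event with
                # probability proportional to total in-degree, otherwise a
                # uniform node; retry to keep per-article targets distinct
                total_weight = len(cite_events) + a * len(nodes)
                if total_weight > 0.0:
                    for _attempt in range(100):
                        if rng.random() * total_weight < len(cite_events):
                            cand = cite_events[int(rng.integers(len(cite_events)))]
                        else:
                            cand = nodes[int(rng.integers(len(nodes)))]
                        if cand not in chosen:
                            target = cand
                            break
                if target is None:
                    if external > 0.0:
                        # nothing citable in corpus yet: cite pre-corpus work
                        target = next_external
                        next_external += 1
                        nodes.append(target)
                    else:
                        continue  # closed corpus: cite fewer, never fail
            chosen.add(target)
            refs.append(target)
            cite_events.append(target)
        if refs and rng.random() < params.dup_rate:
            refs.append(refs[int(rng.integers(len(refs)))])
        if rng.random() < params.self_rate:
            refs.insert(int(rng.integers(len(refs) + 1)), pmid)
        articles.append((pmid, refs))
        nodes.append(pmid)
    return articles


def _clean_refs(pmid: int, refs: list[int]) -> tuple[int, ...]:
    """Parser-equivalent cleanup: drop self-citations, collapse duplicates."""
    seen: set[int] = set()
    out: list[int] = []
    for r in refs:
        if r == pmid or r in seen:
            continue
        seen.add(r)
        out.append(r)
    return tuple(out)


def generate_records(params: GrowthParams) -> list[ArticleRecord]:
    """Cleaned :class:`ArticleRecord` stream for the generated corpus."""
    return [
        ArticleRecord(pmid=pmid, outbound=_clean_refs(pmid, refs), source_path="<synthetic>")
        for pmid, refs in generate_articles(params)
    ]


def generate_network(params: GrowthParams) -> CitationGraph:
    """Generate the citation graph of a synthetic corpus."""
    return build_graph(generate_records(params))


_JATS_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<article article-type="research-article">
  <front>
    <article-meta>
      <article-id pub-id-type="pmid">{pmid}</article-id>
      <title-group><article-title>{title}</article-title></title-group>
    </article-meta>
  </front>
  <body><p>Synthetic article body.</p></body>
  <back>
    <ref-list>
{refs}
    </ref-list>
  </back>
</article>
"""

_REF_TEMPLATE = (
    '      <ref id="r{i}"><element-citation publication-type="journal">'
    '<pub-id pub-id-type="pmid">{cited}</pub-id></element-citation></ref>'
)


def write_jats(
    corpus: Union[CitationGraph, list[tuple[int, list[int]]]],
    directory: Union[str, Path],
) -> list[Path]:
    """Write one minimal JATS file per source article.

    Accepts either a :class:`CitationGraph` (one file per source node, clean
    outbound references) or raw ``(pmid, references)`` pairs as produced by
    :func:`generate_articles` (dirt preserved, for exercising parser rules).
    Cited-only nodes produce no file. Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(corpus, CitationGraph):
        outbound: dict[int, list[int]] = {pmid: [] for pmid in sorted(corpus.sources)}
        for u, v in corpus.edges:
            outbound[u].append(v)
        items = [(pmid, refs) for pmid, refs in outbound.items()]
    else:
        items = list(corpus)
    paths: list[Path] = []
    for pmid, refs in items:
        ref_block = "\n".join(
            _REF_TEMPLATE.format(i=i, cited=cited) for i, cited in enumerate(refs, start=1)
        )
        text = _JATS_TEMPLATE.format(
            pmid=pmid, title=escape(f"Synthetic article {pmid}"), refs=ref_block
        )
        path = directory / f"{pmid}.xml"
        path.write_text(text, encoding="utf-8", newline="\n")
        paths.append(path)
    return paths
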