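# Methods

## Citation graph construction

An article's full-text JATS/NLM XML names the article's own PMID in the
front matter (`article-meta/article-id[@pub-id-type="pmid"]`) and the PMIDs
of its references as `pub-id[@pub-id-type="pmid"]` elements under the
back-matter `ref-list`. Only those two locations are read: a `pub-id`
anywhere else in the document is never emitted as a citation. References
that carry no numeric PMID (books, URLs, DOI-only entries) are dropped
rather than synthesised, because the network is keyed exclusively on PMIDs;
resolving DOIs or PMCIDs to PMIDs is out of scope. Duplicate references are
collapsed and self-citations removed at parse time — both would distort the
out-degree $L(p_j)$ that divides an article's rank among its references. An
article whose own PMID is missing or non-numeric is unidentifiable and is
skipped (with a log record) or aborts the run, per the caller's policy.

The node set of the graph is the union of all parsed-article PMIDs and all
cited PMIDs. A PMID that is cited but whose article was never parsed
becomes a first-class, cited-only node: it can be ranked like any other,
and by construction it is dangling (out-degree 0). Two parsed articles
claiming the same PMID are treated as an error, not merged — silent merging
could hide corpus defects. Nodes are ordered by ascending PMID everywhere,
so every derived artifact (edge lists, score tables) is byte-reproducible.

The inverted citation index is the transpose view: for each node the sorted
list of citing PMIDs and its size, the citation count. By definition the
count equals the node's in-degree and the counts sum to the edge count;
both identities are asserted in the test suite on every graph used.

## PageRank

Scores satisfy

PR(p_i) = (1−d)/N + d · Σ_{p_j ∈ M(p_i)} PR(p_j) / L(p_j)

and are computed by power iteration from the uniform vector 1/N, stopping
when the L1 norm of the change between successive iterates falls below
epsilon, or at `max_iterations` with an explicit non-convergence flag and
warning (the caller decides what to do with an unconverged vector).

Parameters, all dimensionless:

| parameter | default | meaning |
|---|---|---|
| `d` | 0.85 | probability of following a citation rather than teleporting |
| `epsilon` | 1e-5 | L1 stopping threshold between iterates |
| `max_iterations` | 100 | iteration cap; ~100 suffices at d=0.85 since the residual contracts by roughly d per step |

Choices the recurrence itself does not fix:

- **Dangling mass.** Nodes with no outbound citations (most of them
  cited-only PMIDs) would leak probability mass. Their mass is
  redistributed uniformly over all nodes at every iteration — the standard
  choice that keeps the iterate a probability distribution and preserves
  the random-reader interpretation. With this convention the scores sum to
  1 (checked to 1e-9 after every run) and each score is at least the
  teleportation floor (1−d)/N.
- **Convergence metric.** L1 distance between successive iterates, the
  conventional PageRank criterion.
- **Initial vector.** Uniform 1/N; deterministic, no seed involved.
- **Scale.** Scores are probabilities summing to 1, not N-scaled; on a
  multi-million-node corpus top scores are then naturally of order 1e-5.

### Verification oracle

`pagerank_oracle` solves the stationary system exactly: with M the
column-stochastic transition matrix whose dangling columns are replaced by
the uniform column 1/N, it solves the dense linear system
(I − d·M)x = (1−d)/N · 1, whose solution is the power iteration's fixed
point. It refuses graphs above 200 nodes — it exists to check the sparse
iteration, not to replace it. The suite compares iteration (run at a tight
epsilon of 1e-12 so the comparison measures the operator, not the stopping
rule) against the oracle to 1e-8 (L∞) on 100 seeded random graphs of up to
50 nodes plus hand-built cases (cycles, star, chain, isolated node), and
separately cross-checks the oracle against networkx's independent
implementation. Analytic limits are asserted exactly: a symmetric 2-cycle
scores 0.5/0.5, a K-cycle 1/K each, and as d→0 the vector approaches
uniform (tested at d=1e-6 to 1e-4).

## Validation statistics

The validation question is whether PageRank ranks articles the way the
conventional metric does. A uniform sample without replacement of
⌈fraction·N⌉ nodes (default fraction 0.05) is drawn with an explicit,
recorded seed from the ascending-PMID node list; on the sampled
(PageRank, citation count) pairs the package reports Pearson R with its
two-sided significance, and an ordinary least-squares fit with PageRank as
the response and citation count as the predictor (the direction is recorded
in the report, so the transposed reading can be produced as well). No
transform is applied to either variable: the claim being tested is a linear
association on the raw scales. For a simple regression the coefficient of
determination equals the squared Pearson correlation, and the report
asserts that identity to 1e-12. Degenerate inputs are errors, not
NaNs: fewer than 3 pairs, or a constant variable.

Whether such a sample is large enough is answered by the standard
finite-population sample size for estimating a proportion:

n = ⌈ N·x / ((N−1)·E² + x) ⌉,  x = Z²·p·(1−p)

with Z the two-sided normal quantile of the confidence level (1.959964 at
95 %), E the margin of error and p the assumed response distribution (0.5,
the conservative worst case). At N = 6,293,819, 95 % confidence and a 5 %
margin this gives 385; as N→∞ it approaches ⌈384.16⌉ = 385, and at N = 100
it gives 80. The function is non-decreasing in N and non-increasing in E
(property-tested).

Top-N tables list the n highest-PageRank nodes with their citation counts,
ties broken by ascending PMID so the table is deterministic.

## Synthetic corpora

The generator emulates a growing citation corpus with Price-style
cumulative advantage, the minimal mechanism that produces the heavy-tailed
citation-count distributions real corpora show. Articles appear
sequentially; article t draws Poisson(`mean_refs`) references; each
reference is, with probability `external_fraction`, a fresh out-of-corpus
PMID, and otherwise a preferential-attachment draw over *all* existing
nodes with kernel (in-degree + `attachment_offset`), constrained to
distinct targets within one reference list. Two structural points matter
and were deliberate:

- **Out-of-corpus nodes stay citable.** In a real corpus the most heavily
  cited nodes are often articles whose full text is not in the parsed set
  (classic method papers), i.e. dangling nodes with very large citation
  counts. If external PMIDs could be cited only once, a node cited a single
  time by an early hub would inherit a top-10 PageRank while holding
  citation count 1 — a pathology real citation networks do not exhibit, and
  one that (in early versions of the generator) destroyed the
  PageRank/citation-count correlation for some seeds. Keeping external
  nodes inside the attachment pool lets their citation counts grow with
  their rank, as in reality.
- **The corpus origin does not truncate reference lists.** The first
  articles have no predecessors to cite; when `external_fraction > 0`
  their reference draws fall back to fresh out-of-corpus PMIDs — early
  articles cite pre-corpus literature, exactly as the oldest articles of
  any real corpus do. Otherwise the oldest articles would combine the
  largest in-degree (cumulative advantage favours the earliest nodes) with
  a near-zero out-degree, funnelling a macroscopic fraction of total rank
  through one or two references. With `external_fraction = 0` the corpus is
  closed by definition and articles simply cite fewer when targets run out.

Defaults: `n_articles=1000`, `mean_refs=8`, `attachment_offset=1.0`,
`external_fraction=0.10`, `dup_rate=0`, `self_rate=0`. A mean reference
list of 8 distinct in-network targets and a ~10 % out-of-corpus share give
graphs whose in-degree distribution is strongly heavy-tailed at a few
thousand nodes while keeping every test and the acceptance script fast;
`dup_rate`/`self_rate` inject duplicate and self references into the raw
reference lists to exercise the parser's cleanup rules (write-out keeps the
dirt; graph construction resolves it with the same rules the XML parser
applies). In-corpus PMIDs are drawn from a low range (100000+) and external
PMIDs from a disjoint high range (9×10⁸+) so provenance is auditable in any
output. Everything is reproducible from the single integer seed.

What the generator does **not** emulate: publication-date metadata, real
reference-list length distributions (real biomedical lists are longer and
not Poisson), topical community structure, citation of corpus articles
from outside the corpus, and any text content. Consequently a passing
correlation test here shows that the pipeline measures what it claims on a
cumulative-advantage network of this size — not that a particular R value
will be observed on any real corpus, where the correlation is
corpus-specific.

## Problem sizes and runtime

The suite and the acceptance script run on synthetic corpora of 200–5,000
articles (up to ~9,000 nodes and ~40,000 edges), sizes at which power
iteration converges in ~20 iterations and the whole acceptance script
completes in seconds; oracle comparisons use 100 graphs of at most 50
nodes, where a dense solve is exact and cheap. These sizes were chosen so
that every statistical regime the package claims (heavy tails, strong
rank/count correlation, dangling-mass handling) is already visible.

## Known limitations

- The JATS reader targets the PMC-OAS convention for PMID placement; other
  JATS profiles that encode references differently would need an adapted
  XPath.
- PageRank is recomputed from scratch per run; there is no incremental
  update for a growing corpus.
- The correlation analysis reports a linear association on raw scales; for
  heavy-tailed data rank-based measures would be more robust, but the
  linear Pearson/OLS pair is the analysis being reproduced.
- Sampling treats all nodes (parsed and cited-only) as the population; a
  `sources`-restricted analysis can be built from the same primitives but
  is not wired into the CLI.
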