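import pytest
from hypothesis import settings

from citerank.graph import from_edges

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture
def two_cycle():
    """Two articles citing each other."""
    return from_edges([(1, 2), (2, 1)])


@pytest.fixture
def chain3():
    """1 -> 2 -> 3; node 3 is cited-only (dangling)."""
    return from_edges([(1, 2), (2, 3)])


@pytest.fixture
def star5():
    """Five leaves (1..5) each citing the hub (10)."""
    return from_edges([(i, 10) for i in range(1, 6)])


@pytest.fixture
def isolated_plus_cycle():
    """A 2-cycle {1, 2} plus the isolated node 3."""
    return from_edges([(1, 2), (2, 1)], sources=[1, 2, 3])


def jats_document(pmid, refs, extra_pub_ids=()):
    """Minimal JATS article XML with the given PMID and reference PMIDs.

    extra_pub_ids are pub-id elements placed OUTSIDE the ref-list; a correct
    parser must never emit them as citations.
    """
    ref_block = "\n".join(
        f'<ref id="r{i}"><element-citation>'
        f'<pub-id pub-id-type="pmid">{r}</pub-id></element-citation></ref>'
        for i, r in enumerate(refs, 1)
    )
    extra = "\n".join(
        f'<pub-id pub-id-type="pmid">{p}</pub-id>' for p in extra_pub_ids
    )
    return f"""<?xml version="1.0"?>
<article>
  <front><article-meta>
    <article-id pub-id-type="pmid">{pmid}</article-id>
    <article-id pub-id-type="doi">10.1000/synthetic</article-id>
  </article-meta></front>
  <body><p>body text {extra}</p></body>
  <back><ref-list>{ref_block}</ref-list></back>
</article>
"""
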