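"""Exception hierarchy for the citerank pipeline."""


class CiteRankError(Exception):
    """Base class for all citerank errors."""


class MalformedXMLError(CiteRankError):
    """An article file could not be parsed as well-formed XML."""

    def __init__(self, source_path: str, detail: str = "") -> None:
        self.source_path = source_path
        msg = f"malformed XML in {source_path}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class UnidentifiableArticleError(CiteRankError):
    """An article carries no numeric PMID of its own and cannot key the graph."""

    def __init__(self, source_path: str) -> None:
        self.source_path = source_path
        super().__init__(f"unidentifiable article (missing or non-numeric PMID): {source_path}")


class DuplicateArticleError(CiteRankError):
    """Two parsed articles claim the same PMID."""

    def __init__(self, pmid: int) -> None:
        self.pmid = pmid
        super().__init__(f"duplicate article record for PMID {pmid}")


class EdgeListFormatError(CiteRankError):
    """A line of an edge-list TSV is not a pair of integers."""

    def __init__(self, path: str, line_number: int, line: str) -> None:
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: malformed edge-list line {line!r}")


class GraphSizeError(CiteRankError):
    """The dense PageRank oracle refused a graph above its size bound."""


class EmptyGraphError(CiteRankError):
    """PageRank is undefined on an empty graph."""


class InsufficientDataError(CiteRankError):
    """Too few pairs for a correlation or regression."""


class ConstantInputError(CiteRankError):
    """A variable is constant, so the correlation is undefined."""
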