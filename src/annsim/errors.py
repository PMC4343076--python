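"""Exception hierarchy.

All user-facing failures derive from :class:`AnnSimError` so callers can
catch one type at an API boundary.
"""


class AnnSimError(Exception):
    """Base class for all errors raised by this package."""


class OntologyError(AnnSimError):
    """Invalid ontology structure or an unloadable ontology file."""


class CycleError(OntologyError):
    """The child->parent edge set contains a directed cycle.

    Attributes
    ----------
    member : str
        One term that participates in the cycle.
    """

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"ontology is not acyclic: term {member!r} lies on a cycle")


class UnknownTermError(OntologyError):
    """A queried or annotated term is not present in the ontology."""


class NoCommonAncestorError(OntologyError):
    """Two terms share no ancestor (disconnected multi-root DAG)."""


class AnnotationError(AnnSimError):
    """Invalid annotation input (empty file, unknown entity, ...)."""


class HeteroGraphError(AnnSimError):
    """Invalid heterogeneous graph, relation typing, or relevance path."""


class EvaluationError(AnnSimError):
    """Degenerate input to an evaluation statistic."""
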