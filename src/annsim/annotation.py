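"""Annotation graphs: entities annotated with sets of ontology terms.

An annotation graph links scientific entities (drugs, proteins, diseases,
clinical conditions -- the type is up to the caller) to controlled-
vocabulary terms of an :class:`~annsim.ontology.OntologyDAG`.  Annotation
sets are true sets: duplicates collapse, and every retained entity keeps
at least one term.

Terms that do not occur in the ontology are handled by an explicit
policy.  The default is ``"error"``: silent dropping hides upstream data
problems, so it must be opted into with ``unknown_term_policy="drop"``
(dropped terms and emptied entities are logged as warnings).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

from .errors import AnnotationError, UnknownTermError
from .ontology import OntologyDAG

__all__ = ["AnnotationGraph", "load_annotations", "write_annotations"]

logger = logging.getLogger(__name__)


class AnnotationGraph:
    """Map from entity identifiers to non-empty sets of ontology terms."""

    def __init__(
        self,
        annotations: Mapping[str, Iterable[str]],
        ontology: OntologyDAG,
        unknown_term_policy: str = "error",
    ):
        if unknown_term_policy not in ("error", "drop"):
            raise AnnotationError(
                f"unknown_term_policy must be 'error' or 'drop', "
                f"got {unknown_term_policy!r}"
            )
        self.ontology = ontology
        self._ann: dict[str, frozenset[str]] = {}
        for entity, terms in annotations.items():
            termset = frozenset(terms)
            missing = {t for t in termset if t not in ontology}
            if missing and unknown_term_policy == "error":
                term = sorted(missing)[0]
                raise UnknownTermError(
                    f"entity {entity!r} is annotated with term {term!r} "
                    f"which is not in the ontology"
                )
            if missing:
                logger.warning(
                    "entity %r: dropped %d term(s) absent from the ontology: %s",
                    entity, len(missing), sorted(missing),
                )
                termset -= missing
            if not termset:
                if missing:
                    logger.warning(
                        "entity %r removed: no annotations left after dropping "
                        "unknown terms", entity,
                    )
                    continue
                raise AnnotationError(f"entity {entity!r} has an empty annotation set")
            self._ann[entity] = termset

    @property
    def entities(self) -> frozenset[str]:
        return frozenset(self._ann)

    def __contains__(self, entity: str) -> bool:
        return entity in self._ann

    def __len__(self) -> int:
        return len(self._ann)

    def __getitem__(self, entity: str) -> frozenset[str]:
        try:
            return self._ann[entity]
        except KeyError:
            raise AnnotationError(f"unknown entity {entity!r}") from None

    def annotations(self, entity: str) -> frozenset[str]:
        """The annotation term set of ``entity``."""
        return self[entity]

    def annotation_count(self, entity: str) -> int:
        """Number of distinct terms annotating ``entity``."""
        return len(self[entity])

    def items(self):
        return self._ann.items()


def load_annotations(
    path: str | Path,
    ontology: OntologyDAG,
    unknown_term_policy: str = "error",
) -> AnnotationGraph:
    """Load entity annotations from an ``entity<TAB>term`` TSV file.

    ``#``-prefixed lines are comments; duplicate (entity, term) rows
    collapse.  An empty file raises :class:`AnnotationError`.
    """
    path = Path(path)
    pairs: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise AnnotationError(
                    f"{path}:{lineno}: expected entity<TAB>term, "
                    f"got {len(cols)} column(s)"
                )
            pairs.setdefault(cols[0], set()).add(cols[1])
    if not pairs:
        raise AnnotationError(f"annotation file {path} contains no data rows")
    return AnnotationGraph(pairs, ontology, unknown_term_policy=unknown_term_policy)


def write_annotations(AG: AnnotationGraph, path: str | Path) -> None:
    """Write an annotation graph back to entity<TAB>term TSV (sorted, lossless)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for entity in sorted(AG.entities):
            for term in sorted(AG[entity]):
                fh.write(f"{entity}\t{term}\n")
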