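"""Ontology loading and lightweight structural inference.

The knowledge layer mines three OWL axiom families out of an RDF graph —
object-property assertions (individual → individual), data-property
assertions (individual → literal), and class-level assertions (class →
class) — and exposes the subclass/type structure needed to relate an
instance triple to the schema triples it instantiates.

Inference here is deliberately structural: asserted types plus the
transitive superclass closure. No description-logic reasoning
(disjointness, property chains, cardinality) is performed; the dialogue
and QA layers only ever need the closure.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

log = logging.getLogger(__name__)

#: Namespaces whose predicates are structural vocabulary, not domain assertions.
_CORE_NAMESPACES = (str(RDF), str(RDFS), str(OWL), str(XSD))


class AssertionKind(enum.Enum):
    OBJECT_PROPERTY = "object"
    DATA_PROPERTY = "data"
    CLASS = "class"


@dataclass(frozen=True)
class Entity:
    """A named ontology term with a display label.

    The label is the explicit ``rdfs:label`` when one is asserted,
    otherwise the IRI local name with underscores replaced by spaces and
    lowercased. Labels never contain underscores.
    """

    iri: str
    label: str

    def __post_init__(self) -> None:
        if self.iri and not self.label:
            raise ValueError(f"entity {self.iri!r} has an empty label")
        if "_" in self.label:
            raise ValueError(f"label {self.label!r} contains underscores")


@dataclass(frozen=True)
class AssertionTriple:
    """One mined axiom: (domain, property, range) with its family tag.

    ``range`` is an :class:`Entity` for object- and class-level
    assertions and a plain string (the literal's lexical form) for
    data-property assertions.
    """

    domain: Entity
    property: Entity
    range: Entity | str
    kind: AssertionKind

    def __post_init__(self) -> None:
        is_literal = isinstance(self.range, str)
        if (self.kind is AssertionKind.DATA_PROPERTY) != is_literal:
            raise ValueError("kind=DATA_PROPERTY iff range is a literal")

    def labels(self) -> tuple[str, str, str]:
        rng = self.range if isinstance(self.range, str) else self.range.label
        return (self.domain.label, self.property.label, rng)


@dataclass
class KnowledgeBase:
    """Parsed ontology: assertion lists plus subclass/type structure."""

    entities: dict[str, Entity] = field(default_factory=dict)
    object_assertions: list[AssertionTriple] = field(default_factory=list)
    data_assertions: list[AssertionTriple] = field(default_factory=list)
    class_assertions: list[AssertionTriple] = field(default_factory=list)
    #: class IRI -> set of direct superclass IRIs
    subclass_edges: dict[str, set[str]] = field(default_factory=dict)
    #: individual IRI -> set of asserted class IRIs
    type_assertions: dict[str, set[str]] = field(default_factory=dict)
    #: property IRI -> set of direct superproperty IRIs
    subproperty_edges: dict[str, set[str]] = field(default_factory=dict)
    source: str = ""

    def entity(self, iri: str) -> Entity:
        return self.entities[iri]

    def individuals(self) -> list[str]:
        return sorted(self.type_assertions)

    def data_values(self, subject_iri: str, property_local: str) -> list[str]:
        """Literal values of ``subject_iri`` under a property with the given local name."""
        out = [
            str(t.range)
            for t in self.data_assertions
            if t.domain.iri == subject_iri and local_name(t.property.iri) == property_local
        ]
        return sorted(out)

    def object_values(self, subject_iri: str, property_local: str) -> list[str]:
        out = [
            t.range.iri
            for t in self.object_assertions
            if t.domain.iri == subject_iri
            and local_name(t.property.iri) == property_local
            and isinstance(t.range, Entity)
        ]
        return sorted(out)


def local_name(iri: str) -> str:
    """Local fragment of an IRI (after '#' or the last '/')."""
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


def _guess_format(path: Path) -> str:
    if path.suffix.lower() in {".ttl", ".n3"}:
        return "turtle"
    return "xml"


def _label_for(graph: Graph, node: URIRef) -> str:
    explicit = graph.value(node, RDFS.label)
    if explicit is not None:
        return str(explicit).replace("_", " ").strip()
    return local_name(str(node)).replace("_", " ").strip().lower()


def load_ontology(path: str | Path, fmt: str | None = None) -> KnowledgeBase:
    """Parse an RDF/XML or Turtle ontology into a :class:`KnowledgeBase`.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError``
    (carrying the parser's line diagnostics) for unparseable syntax.
    Blank-node classes and blank-node assertion members are skipped with
    a logged warning; the assertion families only hold named terms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ontology file not found: {path}")
    graph = Graph()
    try:
        graph.parse(path.as_posix(), format=fmt or _guess_format(path))
    except Exception as exc:  # rdflib raises a zoo of parser errors
        raise ValueError(f"cannot parse ontology {path}: {exc}") from exc
    return _build_kb(graph, source=str(path))


def _build_kb(graph: Graph, source: str = "") -> KnowledgeBase:
    kb = KnowledgeBase(source=source)

    classes: set[str] = set()
    for s in graph.subjects(RDF.type, OWL.Class):
        if isinstance(s, URIRef):
            classes.add(str(s))
    for s, o in graph.subject_objects(RDFS.subClassOf):
        for node in (s, o):
            if isinstance(node, URIRef):
                classes.add(str(node))
    for o in graph.objects(None, RDF.type):
        if isinstance(o, URIRef) and not str(o).startswith(_CORE_NAMESPACES):
            classes.add(str(o))

    def intern(node: URIRef) -> Entity:
        iri = str(node)
        ent = kb.entities.get(iri)
        if ent is None:
            ent = Entity(iri=iri, label=_label_for(graph, node))
            kb.entities[iri] = ent
        return ent

    for s, o in graph.subject_objects(RDFS.subClassOf):
        if isinstance(s, BNode) or isinstance(o, BNode):
            log.warning("skipping anonymous class in subclass axiom")
            continue
        kb.subclass_edges.setdefault(str(s), set()).add(str(o))
        intern(s), intern(o)

    for s, o in graph.subject_objects(RDFS.subPropertyOf):
        if isinstance(s, URIRef) and isinstance(o, URIRef):
            kb.subproperty_edges.setdefault(str(s), set()).add(str(o))

    for s, o in graph.subject_objects(RDF.type):
        if not isinstance(s, URIRef) or not isinstance(o, URIRef):
            continue
        if str(o).startswith(_CORE_NAMESPACES):
            continue
        if str(s) in classes:
            continue
        kb.type_assertions.setdefault(str(s), set()).add(str(o))
        intern(s), intern(o)

    for s, p, o in sorted(graph, key=lambda t: (str(t[0]), str(t[1]), str(t[2]))):
        if str(p).startswith(_CORE_NAMESPACES):
            continue
        if isinstance(s, BNode) or isinstance(o, BNode):
            log.warning("skipping assertion with anonymous member: %s %s %s", s, p, o)
            continue
        if not isinstance(s, URIRef):
            continue
        prop = intern(p)
        if isinstance(o, Literal):
            kb.data_assertions.append(
                AssertionTriple(intern(s), prop, str(o), AssertionKind.DATA_PROPERTY)
            )
        elif str(s) in classes and str(o) in classes:
            kb.class_assertions.append(
                AssertionTriple(intern(s), prop, intern(o), AssertionKind.CLASS)
            )
        else:
            kb.object_assertions.append(
                AssertionTriple(intern(s), prop, intern(o), AssertionKind.OBJECT_PROPERTY)
            )
    return kb


def superclass_closure(kb: KnowledgeBase, class_iris: set[str]) -> set[str]:
    """Transitive closure of ``class_iris`` under the subclass relation."""
    closed = set(class_iris)
    frontier = list(class_iris)
    while frontier:
        cur = frontier.pop()
        for sup in kb.subclass_edges.get(cur, ()):
            if sup not in closed:
                closed.add(sup)
                frontier.append(sup)
    return closed


def infer_classes(kb: KnowledgeBase, individual: Entity | str) -> set[Entity]:
    """Asserted types of an individual plus their transitive superclasses.

    Raises ``KeyError`` when the individual has no asserted type (it is
    unknown to the type graph).
    """
    iri = individual.iri if isinstance(individual, Entity) else individual
    asserted = kb.type_assertions.get(iri)
    if not asserted:
        raise KeyError(f"unknown individual (no asserted types): {iri}")
    return {kb.entities[c] for c in superclass_closure(kb, set(asserted))}


def _superproperty_closure(kb: KnowledgeBase, prop_iri: str) -> set[str]:
    closed = {prop_iri}
    frontier = [prop_iri]
    while frontier:
        cur = frontier.pop()
        for sup in kb.subproperty_edges.get(cur, ()):
            if sup not in closed:
                closed.add(sup)
                frontier.append(sup)
    return closed


def tbox_assertions_of(kb: KnowledgeBase, triple: AssertionTriple) -> list[AssertionTriple]:
    """Class-level assertions instantiated by an instance triple.

    A class assertion (D, P, R) qualifies when D is among the inferred
    classes of the triple's domain, R among those of its range, and P is
    the triple's property (or one of its declared superproperties).
    Data-property triples have a literal range, which instantiates no
    named class, so they can only match through an empty range — i.e.
    never — mirroring a schema check that is only meaningful for
    instance-to-instance links.
    """
    if triple.kind is AssertionKind.CLASS:
        raise ValueError("tbox_assertions_of expects an instance-level triple")
    try:
        dom_classes = {e.iri for e in infer_classes(kb, triple.domain)}
    except KeyError:
        return []
    if isinstance(triple.range, Entity):
        try:
            rng_classes = {e.iri for e in infer_classes(kb, triple.range)}
        except KeyError:
            return []
    else:
        rng_classes = set()
    props = _superproperty_closure(kb, triple.property.iri)
    out = []
    for ca in kb.class_assertions:
        if (
            ca.domain.iri in dom_classes
            and ca.property.iri in props
            and isinstance(ca.range, Entity)
            and ca.range.iri in rng_classes
        ):
            out.append(ca)
    return out
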