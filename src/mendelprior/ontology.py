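"""OBO ontology parsing, ancestor closure, slim mapping, gene annotation.

Only ``is_a`` edges participate in subsumption. Obsolete terms are retained
but flagged and never traversed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import DataError, ValidationError


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    parents: frozenset
    obsolete: bool = False


@dataclass
class Ontology:
    terms: dict  # term_id -> Term
    root_ids: frozenset = frozenset()

    def __post_init__(self):
        if not self.root_ids:
            self.root_ids = frozenset(
                t.term_id
                for t in self.terms.values()
                if not t.parents and not t.obsolete
            )
        self._children: dict[str, set] | None = None

    def children_of(self, term_id: str) -> set:
        if self._children is None:
            children: dict[str, set] = {tid: set() for tid in self.terms}
            for t in self.terms.values():
                if t.obsolete:
                    continue
                for p in t.parents:
                    children[p].add(t.term_id)
            self._children = children
        if term_id not in self.terms:
            raise DataError(f"unknown term {term_id}", code="unknown_term")
        return set(self._children[term_id])

    def name_of(self, term_id: str) -> str:
        term = self.terms.get(term_id)
        return term.name if term is not None else term_id


def _check_acyclic(terms: Mapping[str, Term]) -> None:
    """Iterative three-colour DFS over is_a; raises naming a cycle member."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {tid: WHITE for tid in terms}
    for start in terms:
        if colour[start] != WHITE:
            continue
        stack = [(start, iter(terms[start].parents))]
        colour[start] = GREY
        while stack:
            node, parents = stack[-1]
            advanced = False
            for p in parents:
                if colour[p] == GREY:
                    raise DataError(
                        f"is_a cycle detected involving term {p}", code="cyclic_ontology"
                    )
                if colour[p] == WHITE:
                    colour[p] = GREY
                    stack.append((p, iter(terms[p].parents)))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()


def parse_obo(stream) -> Ontology:
    """Parse an OBO 1.2 text stream ([Term] stanzas; id/name/is_a/is_obsolete)."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    terms: dict[str, Term] = {}
    cur: dict | None = None

    def flush():
        nonlocal cur
        if cur is None:
            return
        tid = cur.get("id")
        if tid is None:
            raise ValidationError("OBO [Term] stanza without id", code="bad_obo")
        terms[tid] = Term(
            term_id=tid,
            name=cur.get("name", tid),
            parents=frozenset(cur.get("is_a", ())),
            obsolete=cur.get("obsolete", False),
        )
        cur = None

    in_term = False
    for raw in lines:
        line = raw.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if in_term:
                cur = {}
            continue
        if not in_term or cur is None or not line or line.startswith("!"):
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        key = key.strip()
        if key == "id":
            cur["id"] = value
        elif key == "name":
            cur["name"] = value
        elif key == "is_a":
            cur.setdefault("is_a", []).append(value.split("!")[0].strip())
        elif key == "is_obsolete":
            cur["obsolete"] = value.lower().startswith("true")
    flush()

    for term in terms.values():
        for p in term.parents:
            if p not in terms:
                raise DataError(
                    f"term {term.term_id} has dangling parent {p}",
                    code="dangling_parent",
                )
    _check_acyclic(terms)
    return Ontology(terms=terms)


def load_obo(path) -> Ontology:
    with open(path) as fh:
        return parse_obo(fh)


def ancestor_closure(
    term_ids: Iterable[str], ontology: Ontology, include_roots: bool = True
) -> set:
    """Input terms plus all their is_a ancestors (BFS up the DAG)."""
    term_ids = set(term_ids)
    unknown = sorted(
        t for t in term_ids
        if t not in ontology.terms or ontology.terms[t].obsolete
    )
    if unknown:
        raise DataError(
            f"unknown or obsolete term ids: {unknown}", code="unknown_term"
        )
    closure = set(term_ids)
    frontier = list(term_ids)
    while frontier:
        tid = frontier.pop()
        for p in ontology.terms[tid].parents:
            if ontology.terms[p].obsolete or p in closure:
                continue
            closure.add(p)
            frontier.append(p)
    if not include_roots:
        closure -= set(ontology.root_ids) - term_ids
    return closure


def build_slim(ontology: Ontology, root_term_id: str) -> set:
    """Direct non-obsolete children of the given root term."""
    if root_term_id not in ontology.terms:
        raise DataError(f"unknown slim root {root_term_id}", code="unknown_term")
    return ontology.children_of(root_term_id)


def map_to_slim(term_ids: Iterable[str], slim: Iterable[str], ontology: Ontology) -> set:
    """Slim terms reachable upward from any of the given terms."""
    slim = set(slim)
    missing = sorted(s for s in slim if s not in ontology.terms)
    if missing:
        raise DataError(f"slim terms not in ontology: {missing}", code="unknown_term")
    return ancestor_closure(term_ids, ontology) & slim if term_ids else set()


@dataclass
class GeneSetAnnotation:
    """Inverted term -> gene index over a fixed gene background."""

    ontology_label: str
    term_to_genes: dict  # term_id -> frozenset of gene_id
    genome_background: frozenset
    term_names: dict = field(default_factory=dict)
    root_ids: frozenset = frozenset()

    def __post_init__(self):
        for tid, genes in self.term_to_genes.items():
            extra = set(genes) - set(self.genome_background)
            if extra:
                raise DataError(
                    f"term {tid} annotates genes outside the background: "
                    f"{sorted(extra)[:5]}",
                    code="background_mismatch",
                )


def annotate_genes(
    associations: list,
    ontology: Ontology,
    ontology_kind: str,
    label: str | None = None,
) -> GeneSetAnnotation:
    """Propagate disease terms to genes and invert to term -> gene sets.

    A gene's term set is the ancestor closure of the union of direct terms of
    all its diseases. Every gene with at least one association enters the
    background, term-annotated or not.
    """
    if ontology_kind not in ("HPO", "DO"):
        raise ValidationError(
            f"ontology_kind must be HPO or DO, got {ontology_kind!r}",
            code="bad_ontology_kind",
        )
    attr = "hpo_terms" if ontology_kind == "HPO" else "do_terms"
    gene_direct: dict[str, set] = {}
    background = set()
    for assoc in associations:
        background.add(assoc.gene_id)
        terms = getattr(assoc, attr)
        if terms:
            gene_direct.setdefault(assoc.gene_id, set()).update(terms)

    term_to_genes: dict[str, set] = {}
    for gene_id, direct in gene_direct.items():
        for tid in ancestor_closure(direct, ontology):
            term_to_genes.setdefault(tid, set()).add(gene_id)

    return GeneSetAnnotation(
        ontology_label=label or ontology_kind,
        term_to_genes={t: frozenset(g) for t, g in term_to_genes.items()},
        genome_background=frozenset(background),
        term_names={t: ontology.name_of(t) for t in term_to_genes},
        root_ids=ontology.root_ids,
    )


def slim_annotation(
    annotation: GeneSetAnnotation,
    slim: Iterable[str],
    ontology: Ontology,
    label: str | None = None,
) -> GeneSetAnnotation:
    """Restrict a propagated annotation to a slim term set."""
    slim = set(slim)
    return GeneSetAnnotation(
        ontology_label=label or f"{annotation.ontology_label}_slim",
        term_to_genes={
            t: g for t, g in annotation.term_to_genes.items() if t in slim
        },
        genome_background=annotation.genome_background,
        term_names={t: n for t, n in annotation.term_names.items() if t in slim},
        root_ids=frozenset(),
    )


def read_gmt(path, label: str, background: Iterable[str] | None = None) -> GeneSetAnnotation:
    """GMT-style term->gene file for generic pathway databases.

    Columns: set id, set name, then member gene ids. Background defaults to
    the union of all member genes.
    """
    term_to_genes: dict[str, frozenset] = {}
    term_names: dict[str, str] = {}
    all_genes: set = set()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            tid, name, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            term_to_genes[tid] = frozenset(genes)
            term_names[tid] = name
            all_genes.update(genes)
    bg = frozenset(background) if background is not None else frozenset(all_genes)
    return GeneSetAnnotation(
        ontology_label=label,
        term_to_genes=term_to_genes,
        genome_background=bg,
        term_names=term_names,
    )


def read_slim_file(path) -> set:
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}
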