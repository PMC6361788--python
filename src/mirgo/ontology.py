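"""Gene Ontology handling: DAG parsing, annotation loading, propagation,
and construction of per-term balanced training sets.

Annotations obey the true-path rule: an entity annotated to a term is
implicitly annotated to every ancestor reachable through the propagating
relations (is_a and part_of by default).  Training negatives for a term are
drawn from entities that carry at least one annotation but are annotated
neither to the term nor to any of its descendants — an entity annotated to a
child would be a true positive under propagation and must not be labelled
negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

PROPAGATING_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACE_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}


@dataclass
class GOGraph:
    """The GO DAG: terms with namespace/name, typed child->parent edges."""

    terms: dict[str, dict]  # id -> {"name": str, "namespace": "BP|MF|CC"}
    parents: dict[str, set[tuple[str, str]]]  # id -> {(parent_id, relation)}
    alt_ids: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._children: dict[str, set[tuple[str, str]]] = {}
        for child, links in self.parents.items():
            for parent, rel in links:
                self._children.setdefault(parent, set()).add((child, rel))
        self._anc_cache: dict[tuple[str, frozenset], frozenset] = {}
        self._desc_cache: dict[tuple[str, frozenset], frozenset] = {}

    def canonical(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.canonical(term) in self.terms

    def namespace(self, term: str) -> str:
        return self.terms[self.canonical(term)]["namespace"]

    def ancestors(
        self, term: str, relations: frozenset = PROPAGATING_RELATIONS
    ) -> frozenset:
        """All terms reachable from ``term`` via the chosen relations
        (reflexive closure excluded)."""
        term = self.canonical(term)
        relations = frozenset(relations)
        key = (term, relations)
        cached = self._anc_cache.get(key)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = [term]
        while stack:
            cur = stack.pop()
            for parent, rel in self.parents.get(cur, ()):
                if rel in relations and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        result = frozenset(out)
        self._anc_cache[key] = result
        return result

    def descendants(
        self, term: str, relations: frozenset = PROPAGATING_RELATIONS
    ) -> frozenset:
        term = self.canonical(term)
        relations = frozenset(relations)
        key = (term, relations)
        cached = self._desc_cache.get(key)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = [term]
        while stack:
            cur = stack.pop()
            for child, rel in self._children.get(cur, ()):
                if rel in relations and child not in out:
                    out.add(child)
                    stack.append(child)
        result = frozenset(out)
        self._desc_cache[key] = result
        return result

    def roots(self, relations: frozenset = PROPAGATING_RELATIONS) -> set[str]:
        """Terms with no propagating parent — the namespace roots."""
        out = set()
        for term in self.terms:
            if not any(rel in relations for _, rel in self.parents.get(term, ())):
                out.add(term)
        return out


def parse_obo(path) -> GOGraph:
    """Parse an OBO 1.2 ontology into a :class:`GOGraph`.

    is_a and part_of (relationship) edges are captured; obsolete terms are
    flagged and excluded from closures; alt_ids map to canonical ids.  A cycle
    among the propagating relations is an error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)

    terms: dict[str, dict] = {}
    parents: dict[str, set[tuple[str, str]]] = {}
    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()

    for term_id, data in graph.nodes(data=True):
        ns = NAMESPACE_ALIASES.get(data.get("namespace", ""), data.get("namespace", ""))
        if data.get("is_obsolete") in ("true", True):
            obsolete.add(term_id)
            continue
        terms[term_id] = {"name": data.get("name", term_id), "namespace": ns}
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term_id

    for child, parent, rel in graph.edges(keys=True):
        if child in obsolete or parent in obsolete:
            continue
        parents.setdefault(child, set()).add((parent, rel))

    # cycle check over propagating relations only
    check = nx.DiGraph()
    check.add_nodes_from(terms)
    for child, links in parents.items():
        for parent, rel in links:
            if rel in PROPAGATING_RELATIONS:
                check.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(check):
        cycle = nx.find_cycle(check)
        raise ValueError(f"ontology contains a cycle: {cycle}")

    return GOGraph(terms=terms, parents=parents, alt_ids=alt_ids, obsolete=obsolete)


@dataclass
class AnnotationSet:
    """(entity, GO term, evidence code) triples, raw or ancestor-propagated."""

    pairs: set[tuple[str, str, str]]
    propagated: bool = False

    def entities(self) -> set[str]:
        return {e for e, _, _ in self.pairs}

    def terms(self) -> set[str]:
        return {t for _, t, _ in self.pairs}

    def by_entity(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for e, t, _ in self.pairs:
            out.setdefault(e, set()).add(t)
        return out

    def terms_for(self, entity: str) -> set[str]:
        return {t for e, t, _ in self.pairs if e == entity}

    def __len__(self) -> int:
        return len(self.pairs)


GAF_COLUMNS = 17


def load_annotations(path, exclude_evidence: set[str] = frozenset({"IEA"})) -> AnnotationSet:
    """Load a GAF 2.x annotation file.

    Rows whose evidence code is in ``exclude_evidence`` are dropped, as are
    NOT-qualified rows.  Malformed lines are skipped with a warning (an
    aggregate count is logged); a file with only malformed lines is an error.
    """
    pairs: set[tuple[str, str, str]] = set()
    n_bad = 0
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            n_rows += 1
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 13:
                n_bad += 1
                continue
            entity, qualifier, go_id, evidence = cols[1], cols[3], cols[4], cols[6]
            if not entity or not go_id.startswith("GO:") or not evidence:
                n_bad += 1
                continue
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in exclude_evidence:
                continue
            pairs.add((entity, go_id, evidence))
    if n_bad:
        logger.warning("skipped %d malformed GAF lines", n_bad)
    if n_rows > 0 and n_bad == n_rows:
        raise ValueError("all GAF lines malformed")
    return AnnotationSet(pairs=pairs, propagated=False)


def write_gaf(path, rows: list[tuple[str, str, str, str]], db: str = "SYN") -> None:
    """Write minimal GAF 2.1 rows of (entity, qualifier, go_id, evidence)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for entity, qualifier, go_id, evidence in rows:
            cols = [""] * GAF_COLUMNS
            cols[0] = db
            cols[1] = entity
            cols[2] = entity
            cols[3] = qualifier
            cols[4] = go_id
            cols[5] = "REF:0000001"
            cols[6] = evidence
            cols[8] = "P"
            cols[11] = "protein"
            cols[12] = "taxon:9606"
            cols[13] = "20200101"
            cols[14] = db
            fh.write("\t".join(cols) + "\n")


def propagate(
    ann: AnnotationSet,
    go: GOGraph,
    relations: frozenset = PROPAGATING_RELATIONS,
    keep_roots: bool = False,
) -> AnnotationSet:
    """Close an annotation set under the true-path rule.

    Every (entity, term) pair is expanded with the term's ancestors via the
    chosen relations.  Namespace roots are excluded unless ``keep_roots``.
    Terms absent from the ontology pass through unpropagated (with a warning);
    obsolete terms are dropped.
    """
    if ann.propagated:
        return AnnotationSet(pairs=set(ann.pairs), propagated=True)
    roots = set() if keep_roots else go.roots(relations)
    out: set[tuple[str, str, str]] = set()
    unknown: set[str] = set()
    for entity, term, evidence in ann.pairs:
        canon = go.canonical(term)
        if canon in go.obsolete:
            continue
        if canon not in go.terms:
            unknown.add(term)
            out.add((entity, term, evidence))
            continue
        if canon not in roots:
            out.add((entity, canon, evidence))
        for anc in go.ancestors(canon, relations):
            if anc not in roots:
                out.add((entity, anc, evidence))
    if unknown:
        logger.warning(
            "%d annotation terms absent from the ontology (passed through)",
            len(unknown),
        )
    return AnnotationSet(pairs=out, propagated=True)


@dataclass
class TermTrainingSet:
    """Balanced positives/negatives for one GO term's binary classifier."""

    term: str
    positives: list[str]
    negatives: list[str]

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tentity\tlabel\n")
            for e in self.positives:
                fh.write(f"{self.term}\t{e}\t1\n")
            for e in self.negatives:
                fh.write(f"{self.term}\t{e}\t0\n")

    @classmethod
    def read_tsv(cls, path) -> "TermTrainingSet":
        pos: list[str] = []
        neg: list[str] = []
        term = None
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                t, e, label = line.rstrip("\n").split("\t")
                term = t
                (pos if label == "1" else neg).append(e)
        if term is None:
            raise ValueError(f"empty training-set file {path}")
        return cls(term=term, positives=pos, negatives=neg)


def build_term_training_set(
    term: str,
    ann: AnnotationSet,
    go: GOGraph,
    min_pos: int = 10,
    seed: int = 0,
    relations: frozenset = PROPAGATING_RELATIONS,
) -> TermTrainingSet | None:
    """Balanced training set for one term, with descendant-excluding negatives.

    Positives: entities annotated (post-propagation) to the term.  Negative
    pool: entities carrying >=1 annotation but annotated neither to the term
    nor to any of its descendants.  Negatives are sampled uniformly without
    replacement, |negatives| = min(|positives|, pool).  Terms with fewer than
    ``min_pos`` positives yield None (skipped).
    """
    if len(ann.pairs) == 0:
        raise ValueError("empty annotation set")
    if not ann.propagated:
        raise ValueError("annotation set must be propagated first")
    by_entity = ann.by_entity()
    positives = sorted(e for e, ts in by_entity.items() if term in ts)
    if len(positives) < min_pos:
        logger.info("term %s has %d < %d positives; skipped", term, len(positives), min_pos)
        return None
    excluded = {term} | set(go.descendants(term, relations))
    pool = sorted(e for e, ts in by_entity.items() if not (ts & excluded))
    rng = np.random.default_rng(seed)
    k = min(len(positives), len(pool))
    negatives = sorted(rng.choice(pool, size=k, replace=False)) if k else []
    return TermTrainingSet(term=term, positives=positives, negatives=list(negatives))


def build_all_training_sets(
    ann: AnnotationSet,
    go: GOGraph,
    min_pos: int = 10,
    seed: int = 0,
    namespace: str | None = None,
) -> dict[str, TermTrainingSet]:
    """Training sets for every annotated term (optionally one namespace)."""
    terms = sorted(ann.terms())
    out: dict[str, TermTrainingSet] = {}
    for i, term in enumerate(terms):
        if term not in go:
            continue
        if namespace and namespace != "all" and go.namespace(term) != namespace:
            continue
        ts = build_term_training_set(term, ann, go, min_pos=min_pos, seed=seed + i)
        if ts is not None:
            out[term] = ts
    return out
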