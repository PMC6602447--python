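"""Phenotype ontology graph, gene annotations and information content.

The Human Phenotype Ontology (HPO) is a rooted directed acyclic graph of
clinical phenotype terms connected by is-a edges.  Genes are annotated with
the terms whose phenotypes they can cause.  The informativeness of a term is
its *information content*

    IC(t) = -ln( n_genes(t) / N_total )

where ``n_genes(t)`` is the number of genes annotated with ``t`` (optionally
counting annotations propagated up to ancestors, the true-path rule) and
``N_total`` is the number of genes annotated with any term at all.  Rare,
specific phenotypes carry high IC; terms annotated to every gene carry zero.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyError",
    "OntologyTerm",
    "OntologyGraph",
    "AnnotationSet",
    "ICTable",
    "parse_obo",
    "compute_ic",
]


class OntologyError(ValueError):
    """Raised for structural problems: cycles, missing parents, unknown terms."""


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    parents: frozenset[str]
    obsolete: bool = False
    replaced_by: str | None = None


class OntologyGraph:
    """A rooted is-a DAG of ontology terms with memoized closure queries.

    ``_up`` holds one edge per is-a assertion, child -> parent, so ancestors
    of a term are the nodes reachable *from* it and descendants are the nodes
    that reach it.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm],
                 replaced: Mapping[str, str] | None = None):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self._replaced = dict(replaced or {})
        self._up = nx.DiGraph()
        self._up.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parents:
                if p not in self.terms:
                    raise OntologyError(f"term {t.id} has unknown parent {p}")
                self._up.add_edge(t.id, p)
        try:
            cycle = nx.find_cycle(self._up)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise OntologyError(f"is-a cycle detected involving term {cycle[0][0]}")
        self.roots: frozenset[str] = frozenset(
            t.id for t in self.terms.values() if not t.parents)
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._replaced

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map an id through obsolete-term replacements; error if unknown."""
        seen = set()
        while term_id in self._replaced and term_id not in seen:
            seen.add(term_id)
            term_id = self._replaced[term_id]
        if term_id not in self.terms:
            raise OntologyError(f"unknown ontology term {term_id!r}")
        return term_id

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms more general than ``term_id`` (transitive, excluding itself)."""
        t = self.resolve(term_id)
        if t not in self._anc_cache:
            self._anc_cache[t] = frozenset(nx.descendants(self._up, t))
        return self._anc_cache[t]

    def descendants(self, term_id: str) -> frozenset[str]:
        """All terms more specific than ``term_id`` (transitive, excluding itself)."""
        t = self.resolve(term_id)
        if t not in self._desc_cache:
            self._desc_cache[t] = frozenset(nx.ancestors(self._up, t))
        return self._desc_cache[t]


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO file into an :class:`OntologyGraph`.

    Only [Term] stanzas are consumed (id, name, is_a, is_obsolete,
    replaced_by).  Obsolete terms are resolved through ``replaced_by`` when
    present, otherwise dropped with a warning; all references are remapped.
    A cycle among is-a edges or a reference to a missing term is a hard error.
    """
    g = obonet.read_obo(path, ignore_obsolete=False)
    replaced: dict[str, str] = {}
    dropped: list[str] = []
    live: dict[str, dict] = {}
    for node, data in g.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            targets = data.get("replaced_by") or []
            if targets:
                replaced[node] = targets[0]
            else:
                dropped.append(node)
        else:
            live[node] = data
    if dropped:
        logger.warning("dropped %d obsolete term(s) with no replacement: %s",
                       len(dropped), ", ".join(sorted(dropped)[:5]))

    def _resolve(tid: str) -> str | None:
        seen = set()
        while tid in replaced and tid not in seen:
            seen.add(tid)
            tid = replaced[tid]
        if tid in live:
            return tid
        if tid in dropped:
            return None
        raise OntologyError(f"reference to missing term {tid!r}")

    terms: dict[str, OntologyTerm] = {}
    for node, data in live.items():
        parents = set()
        for _, parent, key in g.out_edges(node, keys=True):
            if key != "is_a":
                continue  # part_of etc. are out of scope
            p = _resolve(parent)
            if p is None:
                logger.warning("term %s: parent %s is obsolete with no "
                               "replacement; edge dropped", node, parent)
                continue
            parents.add(p)
        terms[node] = OntologyTerm(id=node, name=data.get("name", node),
                                   parents=frozenset(parents))
    # keep only replacements that land on a live term
    replaced = {k: v for k, v in replaced.items() if _resolve(k) is not None}
    return OntologyGraph(terms, replaced=replaced)


@dataclass
class AnnotationSet:
    """Gene <-> term annotations as asserted (no closure applied).

    ``total_annotated_genes`` is the N of the IC formula: the number of genes
    carrying at least one term.
    """

    gene_to_terms: dict[str, frozenset[str]]
    term_to_genes_direct: dict[str, frozenset[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.gene_to_terms = {g: frozenset(ts) for g, ts in
                              self.gene_to_terms.items() if ts}
        inv: dict[str, set[str]] = {}
        for g, ts in self.gene_to_terms.items():
            for t in ts:
                inv.setdefault(t, set()).add(g)
        self.term_to_genes_direct = {t: frozenset(gs) for t, gs in inv.items()}

    @property
    def total_annotated_genes(self) -> int:
        return len(self.gene_to_terms)

    @classmethod
    def from_pairs(cls, graph: OntologyGraph,
                   pairs: Iterable[tuple[str, str]]) -> tuple["AnnotationSet", int]:
        """Build from (gene, term) rows, resolving terms against ``graph``.

        Returns the set and the number of rows dropped because their term is
        unknown to the ontology after obsolete-term resolution.
        """
        g2t: dict[str, set[str]] = {}
        n_dropped = 0
        for gene, term in pairs:
            try:
                t = graph.resolve(term)
            except OntologyError:
                n_dropped += 1
                continue
            g2t.setdefault(gene, set()).add(t)
        return cls({g: frozenset(ts) for g, ts in g2t.items()}), n_dropped


@dataclass(frozen=True)
class ICTable:
    """Per-term information content in nats; terms with zero genes are absent."""

    ic: Mapping[str, float]

    def get(self, term_id: str, default: float | None = None) -> float | None:
        return self.ic.get(term_id, default)

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def __len__(self) -> int:
        return len(self.ic)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term_id\tic\n")
            for t in sorted(self.ic):
                fh.write(f"{t}\t{self.ic[t]:.10g}\n")


def compute_ic(graph: OntologyGraph, ann: AnnotationSet,
               propagate: bool = True) -> ICTable:
    """Compute IC(t) = -ln(n_genes(t) / N_total) for every annotated term.

    With ``propagate`` (the true-path rule, default) a gene annotated to a
    term also counts for every ancestor of that term, which makes IC
    monotone non-increasing from leaves to roots.
    """
    n_total = ann.total_annotated_genes
    if n_total == 0:
        raise OntologyError("no annotated genes")
    counts: Counter[str] = Counter()
    for terms in ann.gene_to_terms.values():
        tset = set(terms)
        if propagate:
            for t in terms:
                tset.update(graph.ancestors(t))
        counts.update(tset)
    return ICTable({t: -math.log(k / n_total) for t, k in counts.items()})
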