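"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's graph/scoring code paths: traversal
is exhaustive path enumeration over a plain parent dict, and scoring
enumerates all (patient term, gene term) pairs.
"""

from __future__ import annotations

import numpy as np

from hporank.ontology import OntologyGraph, OntologyTerm


def build_graph(parents: dict[str, set[str] | list[str]]) -> OntologyGraph:
    """Construct an OntologyGraph directly from a child -> parents mapping."""
    terms = {t: OntologyTerm(id=t, name=t, parents=frozenset(ps))
             for t, ps in parents.items()}
    return OntologyGraph(terms)


def enumerate_ancestors(parents: dict, t: str) -> set[str]:
    """All nodes reachable upward from t, by exhaustive path enumeration."""
    found: set[str] = set()
    stack = [[t]]
    while stack:
        path = stack.pop()
        for p in parents.get(path[-1], ()):
            if p in path:
                raise ValueError("cycle")
            found.add(p)
            stack.append(path + [p])
    return found


def enumerate_descendants(parents: dict, t: str) -> set[str]:
    return {u for u in parents if u != t and t in enumerate_ancestors(parents, u)}


def random_dag(rng: np.random.Generator, n_nodes: int) -> dict[str, set[str]]:
    """A random DAG: node i may only have parents among nodes < i."""
    parents: dict[str, set[str]] = {"n0": set()}
    for i in range(1, n_nodes):
        k = int(rng.integers(0, min(i, 3) + 1))
        idx = rng.choice(i, size=k, replace=False) if k else []
        parents[f"n{i}"] = {f"n{int(j)}" for j in idx}
    return parents


def brute_force_score(parents: dict, ic: dict[str, float],
                      gene_terms: set[str], patient_terms: list[str],
                      w_direct: float, w_ancestor: float,
                      w_descendant: float) -> float:
    """Enumerate all (patient term, gene term) pairs and classify each by
    explicit path search; best class per patient term, summed."""
    total = 0.0
    for t in dict.fromkeys(patient_terms):
        best = 0.0
        matched_direct = t in gene_terms
        matched_anc = any(t in enumerate_ancestors(parents, gt)
                          for gt in gene_terms)
        matched_desc = any(gt in enumerate_ancestors(parents, t)
                           for gt in gene_terms)
        if matched_direct:
            best = w_direct
        elif matched_anc:
            best = w_ancestor
        elif matched_desc:
            best = w_descendant
        total += best * ic.get(t, 0.0)
    return total


def brute_force_rank(scores: dict[str, float], gene: str) -> int:
    return 1 + sum(1 for g, s in scores.items() if s > scores[gene])
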