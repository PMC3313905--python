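"""Ontology-based overrepresentation analysis (parent-child-union).

Study sets of genes are tested for term overrepresentation against the
common gene set as reference.  Rather than testing each term in
isolation, the parent-child-union method conditions the hypergeometric
universe on the genes annotated to the union of a term's parents,
which suppresses the cascade of false positives that the hierarchy
induces below a genuinely enriched term.

Annotations must be true-path closed (a gene annotated to a term is
annotated to all its ancestors) before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Ontology",
    "propagate_annotations",
    "parent_child_union_ora",
    "categorize_terms",
    "load_obo",
]


@dataclass
class Ontology:
    """A rooted is-a DAG of terms."""

    graph: nx.DiGraph  # edges child -> parent
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("term graph contains a cycle")
        roots = [t for t in self.graph if self.graph.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have a single root, found {roots}")
        self._root = roots[0]

    @classmethod
    def from_edges(cls, edges, names: dict | None = None) -> "Ontology":
        """Build from (child, parent) is-a pairs."""
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        return cls(graph=g, names=names or {})

    @property
    def root(self):
        return self._root

    @property
    def terms(self) -> list:
        return sorted(self.graph.nodes)

    def parents(self, term) -> set:
        return set(self.graph.successors(term))

    def ancestors(self, term) -> set:
        return set(nx.descendants(self.graph, term))  # edges point rootward


def load_obo(path) -> Ontology:
    """Read the id/name/is_a subset of an OBO file.

    Uses obonet when the file parses as full OBO; the resulting graph
    already has child -> parent edges for is_a.
    """
    import obonet

    g = obonet.read_obo(path)
    dg = nx.DiGraph()
    names = {}
    for node, data in g.nodes(data=True):
        dg.add_node(node)
        if "name" in data:
            names[node] = data["name"]
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            dg.add_edge(child, parent)
    return Ontology(graph=dg, names=names)


def propagate_annotations(
    ontology: Ontology, annotations: dict[object, set]
) -> dict[object, set]:
    """True-path closure: each gene inherits every ancestor of its
    directly annotated terms.  Idempotent; annotations to unknown terms
    are dropped with a warning."""
    import logging

    known = set(ontology.graph.nodes)
    closed: dict[object, set] = {}
    for gene, terms in annotations.items():
        bad = set(terms) - known
        if bad:
            logging.getLogger(__name__).warning(
                "gene %s annotated to unknown terms %s; dropped", gene, sorted(bad)
            )
        keep = set(terms) & known
        full = set(keep)
        for t in keep:
            full |= ontology.ancestors(t)
        closed[gene] = full
    return closed


def _genes_of(terms: set, closed: dict[object, set]) -> set:
    return {g for g, ts in closed.items() if ts & terms}


def parent_child_union_ora(
    study: set,
    reference: set,
    ontology: Ontology,
    closed_annotations: dict[object, set],
) -> pd.DataFrame:
    """Parent-child-union overrepresentation of every non-root term.

    For term t with parents P(t): the population is the reference genes
    annotated to the union of P(t); the draws are the study genes in
    that population; successes are reference genes annotated to t
    itself; observed successes are study genes annotated to t.  The
    p-value is the hypergeometric upper tail P(X >= observed).

    Terms with no reference gene in the parent union, or no reference
    gene annotated to the term, are skipped.
    """
    if not study <= reference:
        raise ValueError(
            f"study set must be a subset of the reference; "
            f"{len(study - reference)} genes outside"
        )
    closed = {g: ts for g, ts in closed_annotations.items() if g in reference}
    rows = []
    for t in ontology.terms:
        if t == ontology.root:
            continue
        parents = ontology.parents(t)
        pop = _genes_of(parents, closed)
        term_genes = _genes_of({t}, closed)
        n_pop_parents = len(pop)
        n_pop_term = len(term_genes & pop)
        if n_pop_parents == 0 or n_pop_term == 0:
            continue
        study_pop = study & pop
        n_study_parents = len(study_pop)
        n_study_term = len(term_genes & study_pop)
        p = float(
            stats.hypergeom.sf(
                n_study_term - 1, n_pop_parents, n_pop_term, n_study_parents
            )
        )
        rows.append(
            {
                "term": t,
                "name": ontology.names.get(t, ""),
                "n_pop_parents": n_pop_parents,
                "n_pop_term": n_pop_term,
                "n_study_parents": n_study_parents,
                "n_study_term": n_study_term,
                "p_value": min(p, 1.0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term",
            "name",
            "n_pop_parents",
            "n_pop_term",
            "n_study_parents",
            "n_study_term",
            "p_value",
        ],
    )


def categorize_terms(
    records: pd.DataFrame,
    category_map: dict,
    alpha: float = 0.05,
    correction: str | None = None,
) -> dict[str, bool]:
    """Which functional categories have a significant term.

    ``category_map`` maps term -> category (e.g. F_p for apoptosis
    evasion / cell-cycle progression, F_a for apoptosis induction /
    cell-cycle arrest).  Optional multiple-testing correction:
    'bonferroni' or 'bh' (none by default).
    """
    if records.empty:
        return {}
    p = records["p_value"].to_numpy(dtype=float)
    if correction == "bonferroni":
        p = np.minimum(p * len(p), 1.0)
    elif correction == "bh":
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_i, idx in enumerate(reversed(order), 1):
            k = m - rank_i + 1
            prev = min(prev, p[idx] * m / k)
            adj[idx] = prev
        p = adj
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    sig_terms = records["term"].to_numpy()[p < alpha]
    present: dict[str, bool] = {}
    for cat in sorted(set(category_map.values())):
        present[cat] = any(category_map.get(t) == cat for t in sig_terms)
    return present
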