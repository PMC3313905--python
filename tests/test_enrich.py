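"""Annotation propagation and parent-child-union overrepresentation."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from gcmarray import enrich
from gcmarray.synthetic import generate_toy_ontology


def exact_hypergeom_upper_tail(N, K, n, x):
    """Exhaustive tail sum with exact rational arithmetic."""
    total = Fraction(0)
    for j in range(x, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


def chain_ontology():
    # root <- A <- B
    return enrich.Ontology.from_edges([("A", "root"), ("B", "A")])


class TestOntology:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            enrich.Ontology.from_edges([("A", "B"), ("B", "A")])

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="single root"):
            enrich.Ontology.from_edges([("A", "r1"), ("B", "r2")])

    def test_ancestors_on_diamond(self):
        onto = enrich.Ontology.from_edges(
            [("L", "P1"), ("L", "P2"), ("P1", "root"), ("P2", "root")]
        )
        assert onto.ancestors("L") == {"P1", "P2", "root"}


class TestPropagation:
    def test_chain_closure(self):
        closed = enrich.propagate_annotations(chain_ontology(), {"g1": {"B"}})
        assert closed["g1"] == {"B", "A", "root"}

    def test_idempotent(self):
        onto = chain_ontology()
        once = enrich.propagate_annotations(onto, {"g1": {"B"}, "g2": {"A"}})
        twice = enrich.propagate_annotations(onto, once)
        assert once == twice

    def test_diamond_counts_ancestors_once(self):
        onto = enrich.Ontology.from_edges(
            [("L", "P1"), ("L", "P2"), ("P1", "root"), ("P2", "root")]
        )
        closed = enrich.propagate_annotations(onto, {"g": {"L"}})
        assert closed["g"] == {"L", "P1", "P2", "root"}

    def test_unknown_term_dropped(self):
        closed = enrich.propagate_annotations(chain_ontology(), {"g": {"B", "ZZZ"}})
        assert "ZZZ" not in closed["g"]


class TestParentChildUnionORA:
    def _toy(self):
        onto = chain_ontology()
        genes = [f"g{i}" for i in range(10)]
        direct = {g: {"A"} for g in genes}
        for g in genes[:4]:
            direct[g] = {"B"}
        closed = enrich.propagate_annotations(onto, direct)
        return onto, closed, set(genes)

    def test_counts_and_p_match_hand_enumeration(self):
        onto, closed, reference = self._toy()
        study = {"g0", "g1", "g2", "g5"}  # 3 of 4 term-B genes drawn
        recs = enrich.parent_child_union_ora(study, reference, onto, closed)
        row = recs.set_index("term").loc["B"]
        # parents(B) = {A}: all 10 reference genes annotated to A
        assert row["n_pop_parents"] == 10
        assert row["n_pop_term"] == 4
        assert row["n_study_parents"] == 4
        assert row["n_study_term"] == 3
        expected = exact_hypergeom_upper_tail(10, 4, 4, 3)
        assert row["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_all_toy_instances_match_oracle(self, rng):
        for seed in range(5):
            onto, direct, study, reference = generate_toy_ontology(
                n_terms=8, n_genes=18, planted_enrichment=4.0, seed=seed
            )
            closed = enrich.propagate_annotations(onto, direct)
            recs = enrich.parent_child_union_ora(study, reference, onto, closed)
            for _, r in recs.iterrows():
                expected = exact_hypergeom_upper_tail(
                    int(r["n_pop_parents"]),
                    int(r["n_pop_term"]),
                    int(r["n_study_parents"]),
                    int(r["n_study_term"]),
                )
                assert r["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_study_equal_to_population_gives_p_one(self):
        onto, closed, reference = self._toy()
        recs = enrich.parent_child_union_ora(reference, reference, onto, closed)
        row = recs.set_index("term").loc["B"]
        assert row["p_value"] == pytest.approx(1.0)

    def test_planted_term_attains_minimum_p(self):
        onto, direct, study, reference = generate_toy_ontology(
            n_terms=12, n_genes=60, planted_term="T011",
            planted_enrichment=50.0, seed=4,
        )
        closed = enrich.propagate_annotations(onto, direct)
        recs = enrich.parent_child_union_ora(study, reference, onto, closed)
        best = recs.loc[recs["p_value"].idxmin(), "term"]
        assert best == "T011"

    def test_uniform_study_sets_conservative(self, rng):
        # under random draws, P(p <= alpha) should not exceed alpha by
        # more than sampling noise (the discrete test is conservative)
        onto, closed, reference = self._toy()
        genes = sorted(reference)
        alpha = 0.05
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            study = set(rng.choice(genes, size=4, replace=False))
            recs = enrich.parent_child_union_ora(study, reference, onto, closed)
            p = recs.set_index("term").loc["B", "p_value"]
            hits += p <= alpha
        assert hits / n_sim <= alpha + 0.02

    def test_study_outside_reference_errors(self):
        onto, closed, reference = self._toy()
        with pytest.raises(ValueError, match="subset"):
            enrich.parent_child_union_ora({"zz"}, reference, onto, closed)

    def test_gene_relabeling_invariance(self):
        onto, closed, reference = self._toy()
        study = {"g0", "g1", "g5"}
        recs1 = enrich.parent_child_union_ora(study, reference, onto, closed)
        ren = {g: f"x_{g}" for g in reference}
        closed2 = {ren[g]: t for g, t in closed.items()}
        recs2 = enrich.parent_child_union_ora(
            {ren[g] for g in study}, {ren[g] for g in reference}, onto, closed2
        )
        assert np.allclose(recs1["p_value"], recs2["p_value"])


class TestCategorize:
    def _records(self, p_by_term):
        return pd.DataFrame(
            {
                "term": list(p_by_term),
                "p_value": list(p_by_term.values()),
            }
        )

    def test_no_significant_terms_empty(self):
        recs = self._records({"t1": 0.5, "t2": 0.9})
        present = enrich.categorize_terms(recs, {"t1": "F_a", "t2": "F_p"})
        assert present == {"F_a": False, "F_p": False}

    def test_only_one_category_fires(self):
        recs = self._records({"t1": 0.01, "t2": 0.5})
        present = enrich.categorize_terms(recs, {"t1": "F_a", "t2": "F_p"})
        assert present == {"F_a": True, "F_p": False}

    def test_both_categories_fire(self):
        recs = self._records({"t1": 0.01, "t2": 0.02})
        present = enrich.categorize_terms(recs, {"t1": "F_a", "t2": "F_p"})
        assert present == {"F_a": True, "F_p": True}

    def test_bonferroni_flag(self):
        recs = self._records({f"t{i}": 0.02 for i in range(10)})
        cmap = {f"t{i}": "F_a" for i in range(10)}
        assert enrich.categorize_terms(recs, cmap)["F_a"]
        assert not enrich.categorize_terms(recs, cmap, correction="bonferroni")["F_a"]


class TestOboLoader:
    def test_minimal_obo_roundtrip(self, tmp_path):
        text = (
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root process\n\n"
            "[Term]\nid: GO:0000002\nname: child process\nis_a: GO:0000001\n\n"
            "[Term]\nid: GO:0000003\nname: grandchild\nis_a: GO:0000002\n"
        )
        p = tmp_path / "mini.obo"
        p.write_text(text)
        onto = enrich.load_obo(str(p))
        assert onto.root == "GO:0000001"
        assert onto.ancestors("GO:0000003") == {"GO:0000002", "GO:0000001"}
        assert onto.names["GO:0000002"] == "child process"
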