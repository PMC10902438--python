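from __future__ import annotations

import numpy as np
import pytest

from _oracles import closure_components
from conftest import mutate_protein
from protostrain.pangenome import (
    GeneFamily,
    classify_families,
    cluster_gene_families,
    karlin_altschul_evalue,
    membership_table,
    presence_absence_matrix,
)
from protostrain.seqio import SequenceRecord

P = lambda i, s: SequenceRecord(id=i, seq=s, moltype="protein")  # noqa: E731


def fam(fid, members):
    return GeneFamily(family_id=fid, members=set(members))


class TestClustering:
    def test_dissimilar_proteins_stay_singletons(self, random_protein):
        proteome = {"G1": [random_protein(60, id=f"p{i}") for i in range(4)]}
        families = cluster_gene_families(proteome)
        assert len(families) == 4
        assert all(len(f.members) == 1 for f in families)

    def test_shared_proteins_form_cross_genome_families(self, rng, random_protein):
        base = [random_protein(80, id=f"p{i}") for i in range(3)]
        g1 = [P(f"a{i}", b.seq) for i, b in enumerate(base)]
        g2 = [P(f"b{i}", mutate_protein(b.seq, 8, rng)) for i, b in enumerate(base)]
        families = cluster_gene_families({"G1": g1, "G2": g2})
        assert len(families) == 3
        assert all(len(f.members) == 2 for f in families)

    def test_low_coverage_edge_rejected(self, random_protein, rng):
        # one protein is a high-identity fragment covering ~60% of the other:
        # the 80%-of-both-sequences coverage rule must keep them apart
        full = random_protein(150, id="full")
        fragment = P("frag", full.seq[:90])
        families = cluster_gene_families({"G1": [full], "G2": [fragment]})
        assert len(families) == 2

    def test_low_identity_edge_rejected(self, rng, random_protein):
        base = random_protein(100, id="x")
        far = P("y", mutate_protein(base.seq, 65, rng))  # ~35% identity
        families = cluster_gene_families({"G1": [base], "G2": [far]})
        assert len(families) == 2

    def test_duplicate_gene_id_rejected(self, random_protein):
        rec = random_protein(50, id="dup")
        with pytest.raises(ValueError, match="duplicate gene id"):
            cluster_gene_families({"G1": [rec, rec]})

    def test_conservation_of_genes(self, rng, random_protein):
        base = [random_protein(70, id=f"p{i}") for i in range(3)]
        proteomes = {
            g: [P(f"{g}_p{i}", mutate_protein(b.seq, 5, rng)) for i, b in enumerate(base)]
            for g in ("G1", "G2")
        }
        proteomes["G1"].append(random_protein(60, id="G1_orphan"))
        families = cluster_gene_families(proteomes)
        total_genes = sum(len(v) for v in proteomes.values())
        assert sum(len(f.members) for f in families) == total_genes

    def test_components_equal_transitive_closure_oracle(self, rng, random_protein):
        # random mutation ladders create chains; components must match the
        # brute-force closure of the qualifying-edge graph
        base = random_protein(90, id="b")
        chain = [P(f"g{i}", mutate_protein(base.seq, 4 * i, rng)) for i in range(4)]
        orphan = random_protein(90, id="lone")
        proteomes = {"G1": chain[:2] + [orphan], "G2": chain[2:]}
        families = cluster_gene_families(proteomes)
        # oracle: rebuild the edge graph from scratch with explicit alignments
        from protostrain.pangenome import (
            E_MAX_DEFAULT, MIN_COVERAGE_DEFAULT, MIN_IDENTITY_DEFAULT, SimilarityHit,
        )
        from protostrain.ppos import ScoringScheme, align_proteins, percent_identity

        genes = [("G1", r) for r in proteomes["G1"]] + [("G2", r) for r in proteomes["G2"]]
        db_len = sum(len(r.seq) for _, r in genes)
        n = len(genes)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                pair = align_proteins(genes[i][1], genes[j][1], ScoringScheme(), "local")
                if pair.aligned_columns == 0:
                    continue
                hit = SimilarityHit(
                    query_id=genes[i][1].id, subject_id=genes[j][1].id,
                    identity=percent_identity(pair),
                    coverage_query=pair.coverage_query,
                    coverage_subject=pair.coverage_target,
                    e_value=karlin_altschul_evalue(
                        pair.score, len(genes[i][1].seq), db_len
                    ),
                )
                if hit.passes(E_MAX_DEFAULT, MIN_IDENTITY_DEFAULT, MIN_COVERAGE_DEFAULT):
                    adj[i, j] = adj[j, i] = True
        expected = sorted(
            sorted((genes[i][0], genes[i][1].id) for i in comp)
            for comp in closure_components(adj)
        )
        got = sorted(sorted(f.members) for f in families)
        assert got == expected


class TestEvalue:
    def test_higher_score_means_lower_evalue(self):
        assert karlin_altschul_evalue(100, 200, 10_000) < karlin_altschul_evalue(
            50, 200, 10_000
        )

    def test_family_level_scores_clear_the_cutoff(self, rng, random_protein):
        # a 90%-identity pair of 100-mers has an E-value far below 1e-5
        base = random_protein(100, id="a")
        from protostrain.ppos import ScoringScheme, align_proteins

        pair = align_proteins(base, P("b", mutate_protein(base.seq, 10, rng)),
                              ScoringScheme(), "local")
        assert karlin_altschul_evalue(pair.score, 100, 100_000) < 1e-5


class TestClassification:
    def test_span_rules(self):
        families = [
            fam("f1", [("A", "a1"), ("B", "b1"), ("C", "c1")]),
            fam("f2", [("A", "a2"), ("B", "b2")]),
            fam("f3", [("A", "a3")]),
        ]
        summary = classify_families(families, ["A", "B", "C"])
        assert (summary.core, summary.dispensable, summary.unique) == (1, 1, 1)
        assert summary.pangenome == summary.core + summary.dispensable + summary.unique
        assert summary.tugs_per_genome == {"A": 1, "B": 0, "C": 0}
        assert [f.family_class for f in families] == ["core", "dispensable", "unique"]

    def test_single_genome_families_are_unique(self):
        families = [fam("f1", [("A", "a1")]), fam("f2", [("A", "a2")])]
        summary = classify_families(families, ["A"])
        assert summary.unique == 2 and summary.core == 0

    def test_undeclared_genome_is_an_error(self):
        with pytest.raises(ValueError, match="undeclared"):
            classify_families([fam("f1", [("Z", "z1")])], ["A"])

    def test_adding_a_genome_never_increases_core(self, rng, random_protein):
        base = [random_protein(70, id=f"p{i}") for i in range(4)]
        def proteome(g, subset):
            return [P(f"{g}_p{i}", mutate_protein(base[i].seq, 3, rng)) for i in subset]

        two = {"G1": proteome("G1", range(4)), "G2": proteome("G2", range(4))}
        fam2 = cluster_gene_families(two)
        core2 = classify_families(fam2, list(two)).core
        three = dict(two)
        three["G3"] = proteome("G3", range(2))  # misses two families
        fam3 = cluster_gene_families(three)
        core3 = classify_families(fam3, list(three)).core
        assert core3 <= core2

    def test_planted_structure_recovered_exactly(self):
        from protostrain.synthetic import simulate_proteomes

        proteomes, truth = simulate_proteomes(
            4, core=30, dispensable_rate=0.2, tugs_per_genome=4, divergence=0.05, seed=7
        )
        families = cluster_gene_families(proteomes)
        summary = classify_families(families, list(proteomes))
        assert summary.core == truth.family_structure["core"]
        assert summary.unique == truth.family_structure["unique"]
        assert summary.dispensable == truth.family_structure["dispensable"]
        assert all(n == 4 for n in summary.tugs_per_genome.values())

    def test_mcl_mode_preserves_gene_conservation(self, rng, random_protein):
        base = [random_protein(70, id=f"p{i}") for i in range(3)]
        proteomes = {
            g: [P(f"{g}_p{i}", mutate_protein(b.seq, 5, rng)) for i, b in enumerate(base)]
            for g in ("G1", "G2", "G3")
        }
        families = cluster_gene_families(proteomes, method="mcl")
        assert sum(len(f.members) for f in families) == 9


class TestReports:
    def test_membership_and_presence_absence(self):
        families = [
            fam("f1", [("A", "a1"), ("B", "b1")]),
            fam("f2", [("A", "a2")]),
        ]
        classify_families(families, ["A", "B"])
        mt = membership_table(families)
        assert len(mt) == 3 and set(mt["class"]) == {"core", "unique"}
        pam = presence_absence_matrix(families, ["A", "B"])
        assert pam.loc["f1"].tolist() == [1, 1]
        assert pam.loc["f2"].tolist() == [1, 0]
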