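from __future__ import annotations

import numpy as np
import pytest

from _oracles import affine_dp_score
from conftest import mutate_protein
from protostrain.datasets import load_bbreve_candidate_table
from protostrain.ppos import (
    ScoringScheme,
    align_proteins,
    compute_ppos,
    percent_identity,
    reciprocal_best_hits,
    score_candidates,
    selection_score,
)
from protostrain.seqio import SequenceRecord

P = lambda i, s: SequenceRecord(id=i, seq=s, moltype="protein")  # noqa: E731
SCHEME = ScoringScheme()


class TestAlign:
    def test_identical_sequences_full_identity_and_ppos(self, random_protein):
        rec = random_protein(40)
        pair = align_proteins(rec, rec)
        assert percent_identity(pair) == 100.0
        assert compute_ppos(pair) == 100.0
        assert pair.coverage_query == pair.coverage_target == 1.0

    def test_score_symmetry(self, random_protein):
        a, b = random_protein(30, id="a"), random_protein(25, id="b")
        assert align_proteins(a, b).score == align_proteins(b, a).score

    def test_classic_local_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        pair = align_proteins(P("a", a), P("b", b), mode="local")
        oracle = affine_dp_score(a, b, SCHEME.matrix, mode="local")
        assert pair.score == oracle

    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_random_pairs_match_dp_oracle(self, mode, rng, random_protein):
        oracle_mode = "local" if mode == "local" else "global_free"
        for trial in range(12):
            a = random_protein(int(rng.integers(8, 30)), id="a")
            b = random_protein(int(rng.integers(8, 30)), id="b")
            pair = align_proteins(a, b, mode=mode)
            assert pair.score == affine_dp_score(a.seq, b.seq, SCHEME.matrix, mode=oracle_mode)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_proteins(P("a", ""), P("b", "MKV"))


class TestPpos:
    def test_direct_ratio(self):
        from protostrain.ppos import OrthologPair

        pair = OrthologPair(
            query_id="q", target_id="t", aligned_columns=50, identical=40,
            positives=48, coverage_query=1.0, coverage_target=1.0,
        )
        assert compute_ppos(pair) == pytest.approx(96.0)

    def test_ppos_at_least_percent_identity(self, rng, random_protein):
        for _ in range(10):
            a = random_protein(30, id="a")
            b = P("b", mutate_protein(a.seq, 5, rng))
            pair = align_proteins(a, b)
            assert compute_ppos(pair) >= percent_identity(pair)

    def test_ppos_non_increasing_along_mutation_ladder(self, rng, random_protein):
        base = random_protein(120, id="base")
        ppos_vals = []
        seq = base.seq
        for n_subs, lid in [(0, "m0"), (8, "m1"), (20, "m2"), (40, "m3")]:
            mutant = P(lid, mutate_protein(base.seq, n_subs, rng))
            ppos_vals.append(compute_ppos(align_proteins(base, mutant)))
        assert all(a >= b for a, b in zip(ppos_vals, ppos_vals[1:]))

    def test_zero_columns_is_an_error(self):
        from protostrain.ppos import OrthologPair

        pair = OrthologPair(
            query_id="q", target_id="t", aligned_columns=0, identical=0,
            positives=0, coverage_query=1.0, coverage_target=1.0,
        )
        with pytest.raises(ValueError, match="zero aligned columns"):
            compute_ppos(pair)


class TestRbh:
    def test_identical_proteomes_self_pairs(self, random_protein):
        proteome = [random_protein(30, id=f"p{i}") for i in range(4)]
        pairs = reciprocal_best_hits(proteome, proteome)
        assert len(pairs) == 4
        assert all(p.query_id == p.target_id for p in pairs)

    def test_planted_orthology_recovered(self, rng, random_protein):
        # 3x3 with one member diverged: RBH must still match planted orthologs
        qs = [random_protein(60, id=f"q{i}") for i in range(3)]
        ts = [P(f"t{i}", q.seq) for i, q in enumerate(qs)]
        ts[1] = P("t1", mutate_protein(qs[1].seq, 10, rng))
        pairs = reciprocal_best_hits(qs, ts, prefilter=False)
        mapping = {p.query_id: p.target_id for p in pairs}
        assert mapping == {"q0": "t0", "q1": "t1", "q2": "t2"}

    def test_equal_score_paralogs_break_ties_lexicographically(self, random_protein):
        q = [random_protein(40, id="q0")]
        t = [P("tb", q[0].seq), P("ta", q[0].seq)]  # identical duplicates
        pairs = reciprocal_best_hits(q, t, prefilter=False)
        assert len(pairs) == 1 and pairs[0].target_id == "ta"

    def test_each_protein_in_at_most_one_pair(self, rng, random_protein):
        qs = [random_protein(40, id=f"q{i}") for i in range(5)]
        ts = [P(f"t{i}", mutate_protein(q.seq, 3, rng)) for i, q in enumerate(qs)]
        pairs = reciprocal_best_hits(qs, ts)
        assert len({p.query_id for p in pairs}) == len(pairs)
        assert len({p.target_id for p in pairs}) == len(pairs)


class TestScoreCandidates:
    def test_published_top_score_from_printed_inputs(self):
        # ANI 98.2 x avg PPOS 96.43; printed table value 9469.6 comes from
        # unrounded inputs and agrees within 0.01% relative tolerance
        score = selection_score(98.2, 96.43)
        assert score == pytest.approx(9469.426, abs=1e-3)
        assert abs(score - 9469.6) / 9469.6 < 1e-4

    def test_perfect_candidate_scores_10000(self):
        assert selection_score(100.0, 100.0) == 10000.0

    def test_published_candidate_table_is_internally_consistent(self):
        # printed ANI/PPOS are rounded while printed scores come from
        # unrounded inputs, so agreement is to ~0.1%
        df = load_bbreve_candidate_table()
        for row in df.itertuples():
            assert selection_score(row.ani, row.avg_ppos) == pytest.approx(
                row.published_score, rel=1e-3
            )

    def test_prototype_as_candidate_ranks_first_with_ppos_100(self, rng, random_protein):
        proto = [random_protein(50, id=f"p{i}") for i in range(3)]
        diverged = [P(f"d{i}", mutate_protein(p.seq, 8, rng)) for i, p in enumerate(proto)]
        reports = score_candidates(
            [("self", proto, 100.0), ("other", diverged, 99.0)], "proto", proto,
            prefilter=False,
        )
        assert reports[0].candidate_id == "self"
        assert reports[0].avg_ppos == 100.0
        assert reports[0].score == 10000.0

    def test_planted_divergence_order_recovered(self, rng, random_protein):
        proto = [random_protein(80, id=f"p{i}") for i in range(4)]
        candidates = []
        for cand_id, n_subs, ani in [("near", 2, 99.0), ("mid", 10, 97.0), ("far", 25, 95.0)]:
            proteome = [P(f"{cand_id}{i}", mutate_protein(p.seq, n_subs, rng))
                        for i, p in enumerate(proto)]
            candidates.append((cand_id, proteome, ani))
        reports = score_candidates(candidates, "proto", proto, prefilter=False)
        assert [r.candidate_id for r in reports] == ["near", "mid", "far"]

    def test_candidate_without_orthologs_excluded_with_warning(self, random_protein):
        proto = [random_protein(60, id="p0")]
        alien = [random_protein(60, id="x0")]  # shares no words with proto
        with pytest.warns(UserWarning, match="no ortholog pairs"):
            reports = score_candidates([("alien", alien, 90.0)], "proto", proto)
        assert reports[0].avg_ppos is None

    def test_length_weighted_aggregation_differs_when_lengths_do(self, rng, random_protein):
        proto = [random_protein(40, id="s"), random_protein(160, id="l")]
        cand = [P("s", mutate_protein(proto[0].seq, 10, rng)), P("l", proto[1].seq)]
        mean_r = score_candidates([("c", cand, 99.0)], "p", proto, prefilter=False)[0]
        lw_r = score_candidates(
            [("c", cand, 99.0)], "p", proto, aggregation="length_weighted", prefilter=False
        )[0]
        assert lw_r.avg_ppos > mean_r.avg_ppos  # long perfect pair dominates
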