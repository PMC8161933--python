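"""Observation model, substitution matrix, per-base and per-candidate scores."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emmul.io_alignments import (
    CandidateLocation,
    MultireadRecord,
    ReadAlignment,
    ReferenceGenome,
    build_unique_index,
)
from emmul.scoring import (
    ObservationModel,
    PositionScorer,
    ScoringMatrix,
    agreement_probability,
    build_observation_model,
    default_sigma,
    score_base_vs_reference,
    score_base_vs_unique_stack,
    select_by_margin,
)

import _oracles as oracle

BASES = "ACGT"


class TestScoringMatrix:
    def test_ot_entries(self):
        m = ScoringMatrix.for_strand("OT")
        assert m.score("A", "A") == 6
        assert m.score("C", "T") == 3  # converted C tolerated
        assert m.score("T", "T") == 3  # read T is ambiguous evidence
        assert m.score("A", "N") == -25
        assert m.score("N", "N") == 25
        assert m.score("G", "T") == -18

    def test_ob_is_complement_mirror(self):
        ob = ScoringMatrix.for_strand("OB")
        assert ob.score("G", "A") == 3  # converted bottom-strand C
        assert ob.score("A", "A") == 3
        assert ob.score("T", "T") == 6
        ot = ScoringMatrix.for_strand("OT")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        for r in "ACGTN":
            for q in "ACGTN":
                assert ob.score(r, q) == ot.score(comp[r], comp[q])

    def test_row_totals(self):
        m = ScoringMatrix.for_strand("OT")
        assert m.total("A") == -48
        assert m.total("C") == -27
        assert m.total("T") == -51


class TestObservationModel:
    def test_fully_methylated_no_snp(self):
        m = build_observation_model(0.0, 1.0, 1.0)
        assert m.prob("C", "C", "OT", context=1) == 1.0
        assert m.prob("T", "C", "OT", context=1) == 0.0

    def test_direct_substitution(self):
        m = build_observation_model(0.0, 0.7, 0.0)
        assert m.prob("T", "C", "OT", context=1) == pytest.approx(0.3)
        assert m.prob("C", "C", "OT", context=1) == pytest.approx(0.7)

    def test_full_table_matches_enumeration(self):
        m = build_observation_model(0.001, 0.7, 0.005)
        for strand in ("OT", "OB"):
            for ctx in (0, 1, 2):
                for gs in BASES:
                    for mk in BASES:
                        expected = oracle.obs_prob(mk, gs, 0.001, 0.7, 0.005, strand, ctx)
                        assert m.prob(mk, gs, strand, ctx) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        snp=st.floats(0, 1), m_cpg=st.floats(0, 1), m_ch=st.floats(0, 1),
    )
    def test_rows_sum_to_one(self, snp, m_cpg, m_ch):
        model = build_observation_model(snp, m_cpg, m_ch)
        for strand in ("OT", "OB"):
            sums = model.tables[strand][:, :4, :4].sum(axis=2)
            assert np.allclose(sums, 1.0, atol=1e-9)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            build_observation_model(1.5, 0.7, 0.005)


class TestReferenceScore:
    def test_certain_observation_returns_matrix_score(self):
        m = build_observation_model(0.0, 1.0, 1.0)
        mat = ScoringMatrix.for_strand("OT")
        # P(C|C)=1 in CpG context under full methylation, no SNPs
        assert score_base_vs_reference("C", "C", m, mat, "OT", 1) == 6.0

    def test_hand_evaluated_converted_cytosine(self):
        # ref C in CpG, snp 0.001, m_cpg 0.7, read T:
        # P = 0.001/3 + 0.999*0.3; score = P*3 + (1-P)*((-27) - 3) = -20.0989
        m = build_observation_model(0.001, 0.7, 0.005)
        mat = ScoringMatrix.for_strand("OT")
        got = score_base_vs_reference("T", "C", m, mat, "OT", 1)
        assert got == pytest.approx(-20.0989, abs=1e-9)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            snp, m_cpg, m_ch = rng.random(3)
            model = build_observation_model(snp, m_cpg, m_ch)
            strand = rng.choice(["OT", "OB"])
            mat = ScoringMatrix.for_strand(strand)
            ctx = int(rng.integers(0, 3))
            gs, mk = rng.choice(list(BASES), 2)
            expected = oracle.eq4(mk, gs, snp, m_cpg, m_ch, strand, ctx)
            assert score_base_vs_reference(mk, gs, model, mat, strand, ctx) == pytest.approx(
                expected, abs=1e-9
            )


class TestAgreementProbability:
    def test_corrected_mode_values(self):
        assert agreement_probability("A", "A", 0.01, 0.01) == pytest.approx(0.9801)
        assert agreement_probability("A", "C", 0.01, 0.01) == pytest.approx(0.0199)

    def test_literal_mode_swaps_branches(self):
        assert agreement_probability("A", "A", 0.01, 0.01, "literal") == pytest.approx(0.0199)
        assert agreement_probability("A", "C", 0.01, 0.01, "literal") == pytest.approx(0.9801)

    def test_error_free_limit(self):
        assert agreement_probability("A", "A", 1e-12, 1e-12) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(e1=st.floats(1e-6, 1), e2=st.floats(1e-6, 1))
    def test_symmetry_in_eps(self, e1, e2):
        assert agreement_probability("A", "A", e1, e2) == agreement_probability("A", "A", e2, e1)


class TestUniqueStackScore:
    def test_mean_of_one(self):
        mat = ScoringMatrix.for_strand("OT")
        one = score_base_vs_unique_stack("A", [("A", 0.01)], 0.01, mat)
        assert one == pytest.approx(oracle.eq67("A", [("A", 0.01)], 0.01))

    def test_identical_stack_equals_single(self):
        mat = ScoringMatrix.for_strand("OT")
        one = score_base_vs_unique_stack("C", [("T", 0.02)], 0.01, mat)
        three = score_base_vs_unique_stack("C", [("T", 0.02)] * 3, 0.01, mat)
        assert three == pytest.approx(one)

    def test_random_stacks_match_brute_force(self):
        rng = np.random.default_rng(11)
        mat = ScoringMatrix.for_strand("OT")
        for _ in range(100):
            n = int(rng.integers(1, 8))
            stack = [(rng.choice(list(BASES)), float(rng.uniform(1e-4, 0.3))) for _ in range(n)]
            mk = rng.choice(list(BASES))
            eps_k = float(rng.uniform(1e-4, 0.3))
            assert score_base_vs_unique_stack(mk, stack, eps_k, mat) == pytest.approx(
                oracle.eq67(mk, stack, eps_k), abs=1e-12
            )

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            score_base_vs_unique_stack("A", [], 0.01, ScoringMatrix.for_strand("OT"))


def _random_fixture(rng, L=200, K=10, n_unique=3):
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
    genome = ReferenceGenome({"c": ref})
    unique = []
    for i in range(n_unique):
        s = int(rng.integers(0, L - K))
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, size=K))
        q = rng.integers(10, 40, size=K)
        unique.append(ReadAlignment(f"u{i}", "c", s, "OT", False, bases, q, [("M", K)]))
    read = "".join("ACGT"[i] for i in rng.integers(0, 4, size=K))
    quals = rng.integers(10, 40, size=K)
    starts = rng.choice(L - K, size=2, replace=False)
    cands = [CandidateLocation("c", int(s), "OT", False, [("M", K)]) for s in sorted(starts)]
    m = MultireadRecord("m0", read, quals, cands)
    return genome, unique, m


class TestPositionScore:
    def _scorer(self, genome, unique, snp=0.001, m_cpg=0.7, m_ch=0.005):
        idx = build_unique_index(unique, genome)
        model = build_observation_model(snp, m_cpg, m_ch)
        return PositionScorer(genome, idx, model)

    def test_no_overlap_substitution_rule(self):
        rng = np.random.default_rng(1)
        genome, _, m = _random_fixture(rng, n_unique=0)
        scorer = self._scorer(genome, [])
        ps = scorer.score(m, 0)
        assert ps.n_overlap == 0
        assert ps.s_unique == ps.s_ref
        assert ps.s_j == ps.s_ref

    def test_matches_full_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        eps_map = lambda q: np.maximum(10.0 ** (-q / 10.0), 1e-4)
        for trial in range(100):
            genome, unique, m = _random_fixture(rng, n_unique=int(rng.integers(0, 5)))
            scorer = self._scorer(genome, unique)
            ur = [(u.start, u.bases, list(eps_map(u.quals.astype(float)))) for u in unique]
            for j in (0, 1):
                got = scorer.score(m, j)
                expected = oracle.eq8(
                    genome.sequences["c"], m.bases, m.candidates[j].start, "OT",
                    ur, 0.001, 0.7, 0.005,
                    read_eps=list(eps_map(m.quals.astype(float))),
                )
                assert got.s_j == pytest.approx(expected, abs=1e-9), trial

    def test_determinism(self):
        rng = np.random.default_rng(9)
        genome, unique, m = _random_fixture(rng)
        s1 = self._scorer(genome, unique).score(m, 0)
        s2 = self._scorer(genome, unique).score(m, 0)
        assert (s1.s_ref, s1.s_unique, s1.s_j) == (s2.s_ref, s2.s_unique, s2.s_j)

    def test_strand_symmetry(self):
        """Mirroring the fixture (revcomp genome, OT<->OB) leaves S_j unchanged."""
        from emmul.io_alignments import revcomp

        rng = np.random.default_rng(13)
        genome, unique, m = _random_fixture(rng, n_unique=3)
        L = genome.lengths["c"]
        s_fwd = [self._scorer(genome, unique).score(m, j).s_j for j in range(m.q)]

        mirrored = ReferenceGenome({"c": revcomp(genome.sequences["c"])})
        unique_m = [
            ReadAlignment(u.read_id, "c", L - u.ref_span()[1], "OB", True,
                          revcomp(u.bases), u.quals[::-1], u.cigar)
            for u in unique
        ]
        cands_m = [
            CandidateLocation("c", L - c.ref_span()[1], "OB", True, c.cigar)
            for c in m.candidates
        ]
        # sequenced-orientation bases of an OB read are the revcomp of its
        # genome-forward window, i.e. the original read string
        m_m = MultireadRecord(m.read_id, m.bases, m.quals, cands_m)
        s_rev = [self._scorer(mirrored, unique_m).score(m_m, j).s_j for j in range(m_m.q)]
        assert s_rev == pytest.approx(s_fwd, abs=1e-9)

    def test_discrimination_margin_grows_with_divergence(self):
        """On an error-free fixture the true window wins, by more as the decoy
        accumulates distinguishing bases."""
        rng = np.random.default_rng(21)
        K, L = 40, 400
        ref = list("ACGT"[i] for i in rng.integers(0, 4, size=L))
        ref[200 : 200 + K] = ref[50 : 50 + K]  # identical decoy at 200
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}
        margins = []
        for d in (1, 3, 6, 10):
            refd = list(ref)
            for off in range(d):
                pos = 200 + 2 + off * 3
                refd[pos] = sub[refd[pos]]
            genome = ReferenceGenome({"c": "".join(refd)})
            bases = genome.sequences["c"][50 : 50 + K]
            cands = [
                CandidateLocation("c", 50, "OT", False, [("M", K)]),
                CandidateLocation("c", 200, "OT", False, [("M", K)]),
            ]
            m = MultireadRecord("m", bases, np.full(K, 40), cands)
            scorer = self._scorer(genome, [])
            s_true, s_decoy = scorer.score(m, 0).s_j, scorer.score(m, 1).s_j
            assert s_true > s_decoy
            margins.append(s_true - s_decoy)
        assert all(b > a for a, b in zip(margins, margins[1:]))

    def test_out_of_bounds_candidate_rejected(self):
        genome = ReferenceGenome({"c": "ACGT" * 10})
        cands = [
            CandidateLocation("c", 0, "OT", False, [("M", 10)]),
            CandidateLocation("c", 35, "OT", False, [("M", 10)]),
        ]
        m = MultireadRecord("m", "ACGTACGTAC", np.full(10, 30), cands)
        scorer = self._scorer(genome, [])
        with pytest.raises(ValueError, match="exceeds"):
            scorer.score(m, 1)


class TestSelectByMargin:
    def _scores(self, values):
        from emmul.scoring import PositionScore

        return [
            PositionScore("m", j, "c", j * 100, "OT", v, v, v, 0)
            for j, v in enumerate(values)
        ]

    def test_clear_margin_assigns_argmax(self):
        a = select_by_margin(self._scores([10, 3]), sigma=5)
        assert a is not None and a.candidate_index == 0
        assert a.margin == pytest.approx(7)
        assert a.stage == "score"

    def test_insufficient_margin_defers(self):
        assert select_by_margin(self._scores([10, 8]), sigma=5) is None

    def test_tie_always_defers(self):
        assert select_by_margin(self._scores([10, 10]), sigma=0) is None

    def test_single_candidate_assigned(self):
        a = select_by_margin(self._scores([4]), sigma=100)
        assert a is not None and a.candidate_index == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_by_margin([], sigma=1)


def test_default_sigma_scales_with_read_length():
    assert default_sigma(100) == pytest.approx(12.0)
    assert default_sigma(50) == pytest.approx(6.0)
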