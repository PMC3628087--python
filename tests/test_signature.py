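"""Pyrimidine orientation, spectra, contexts, PFMs and motif similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import kataegis as kg
from kataegis.catalog import COMPLEMENT, MutationRecord
from kataegis.signature import ContextPFM, _draw_null_pfm
from tests.conftest import make_catalog


class TestOrientation:
    @pytest.mark.parametrize(
        "ref, alt, strand, change",
        [
            ("G", "A", "minus", "C>T"),
            ("C", "G", "plus", "C>G"),
            ("G", "C", "minus", "C>G"),
            ("G", "T", "minus", "C>A"),
            ("C", "T", "plus", "C>T"),
        ],
    )
    def test_cg_pair_mapping(self, ref, alt, strand, change):
        rec = MutationRecord("c1", "chr1", 100, ref, alt)
        oriented = kg.orient_to_pyrimidine(rec)
        assert (oriented.pyr_strand, oriented.change) == (strand, change)
        assert not oriented.at_pair

    def test_at_pair_flagged(self):
        oriented = kg.orient_to_pyrimidine(MutationRecord("c1", "chr1", 100, "A", "T"))
        assert oriented.at_pair and oriented.change is None

    def test_complement_is_involution(self):
        for b in "ACGT":
            assert COMPLEMENT[COMPLEMENT[b]] == b

    def test_orientation_is_idempotent_on_pyrimidine_records(self):
        # a plus-strand C record maps to itself: re-orienting changes nothing
        rec = MutationRecord("c1", "chr1", 100, "C", "A")
        o1 = kg.orient_to_pyrimidine(rec)
        o2 = kg.orient_to_pyrimidine(o1.record)
        assert o1 == o2

    def test_vectorized_orientation_matches_recordwise(self):
        cat = make_catalog(
            [
                ("c1", "chr1", 1, "C", "T"),
                ("c1", "chr1", 2, "G", "C"),
                ("c1", "chr1", 3, "A", "G"),
            ]
        )
        df = kg.orient_catalog(cat.df)
        assert list(df["change"]) == ["C>T", "C>G", ""]
        assert list(df["pyr_strand"]) == ["plus", "minus", ""]
        assert list(df["at_pair"]) == [False, False, True]


class TestSpectrum:
    def test_counts_and_percentages(self):
        cat = make_catalog(
            [
                ("c1", "chr1", 1, "C", "T"),
                ("c1", "chr1", 10, "G", "A"),  # C>T on minus
                ("c1", "chr1", 20, "C", "G"),
                ("c1", "chr1", 30, "C", "A"),
            ]
        )
        s = kg.spectrum(cat, "demo")
        assert s.counts == {"C>T": 2, "C>G": 1, "C>A": 1}
        assert s.percentages == {"C>T": 50.0, "C>G": 25.0, "C>A": 25.0}
        assert s.transversion_fraction == pytest.approx(0.5)

    def test_at_pairs_kept_in_totals_but_not_percentages(self):
        cat = make_catalog(
            [("c1", "chr1", 1, "C", "T"), ("c1", "chr1", 2, "A", "T")]
        )
        s = kg.spectrum(cat)
        assert s.n_total == 2 and s.n_at_pairs == 1
        assert s.percentages == {"C>T": 100.0, "C>G": 0.0, "C>A": 0.0}

    def test_empty_stratum_flagged_undefined(self):
        s = kg.spectrum([])
        assert s.percentages is None
        assert s.transition_fraction is None

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        alts = {"C": "TGA", "G": "ACT"}
        rows = []
        for i in range(200):
            ref = "C" if rng.random() < 0.5 else "G"
            rows.append(("c1", "chr1", i + 1, ref, alts[ref][rng.integers(3)]))
        s = kg.spectrum(make_catalog(rows))
        assert sum(s.percentages.values()) == pytest.approx(100.0, abs=1e-9)


class TestStrandCoordination:
    def test_majority_c(self):
        pol, base = kg.strand_coordination(np.array(list("CCGCC")))
        assert (pol, base) == (pytest.approx(0.8), "C")

    def test_all_g(self):
        pol, base = kg.strand_coordination(np.array(list("GGGG")))
        assert (pol, base) == (1.0, "G")

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            kg.strand_coordination(np.array(["C"]))


class TestContexts:
    def _genome(self, seq):
        return kg.GenomeModel(
            names=["chr1"], lengths={"chr1": len(seq)}, sequence={"chr1": seq}
        )

    def test_plus_strand_context_read_directly(self):
        genome = self._genome("ATTCG")
        cat = make_catalog([("c1", "chr1", 4, "C", "T")])
        contexts, skipped = kg.extract_contexts(cat, genome)
        assert contexts == ["TT"] and skipped == 0  # (-2, -1) order

    def test_minus_strand_context_is_reverse_complemented(self):
        # G>A at pos 3 of ACGAA: pyrimidine strand reads complement of
        # positions 5 and 4 for offsets -2 and -1
        genome = self._genome("ACGAA")
        cat = make_catalog([("c1", "chr1", 3, "G", "A")])
        contexts, skipped = kg.extract_contexts(cat, genome)
        assert contexts == ["TT"] and skipped == 0

    def test_boundary_sites_skipped_and_counted(self):
        genome = self._genome("CCGTT")
        cat = make_catalog(
            [("c1", "chr1", 1, "C", "T"), ("c1", "chr1", 4, "T", "C")]
        )
        contexts, skipped = kg.extract_contexts(cat, genome)
        assert contexts == [] and skipped == 1  # A:T record ignored entirely

    def test_requires_sequence(self, lengths_only_genome):
        cat = make_catalog([("c1", "chrI", 100, "C", "T")])
        with pytest.raises(ValueError, match="sequence"):
            kg.extract_contexts(cat, lengths_only_genome)


class TestBuildPFM:
    def test_counting(self):
        pfm = kg.build_pfm(["TT", "TA"])
        assert pfm.base_fraction(-2, "T") == 1.0
        assert pfm.base_fraction(-1, "T") == 0.5
        assert pfm.base_fraction(-1, "A") == 0.5
        assert pfm.n_sites == 2

    def test_background_normalization_identity(self):
        # observed composition equal to the background -> uniform columns
        contexts = ["AT"] * 10 + ["CT"] * 20 + ["GT"] * 30 + ["TT"] * 40
        bg_m2 = np.array([0.1, 0.2, 0.3, 0.4])
        bg = np.vstack([bg_m2, [0.0, 0.0, 0.0, 1.0]])
        pfm = kg.build_pfm(contexts, background=bg)
        assert np.allclose(pfm.column(-2), 0.25)
        assert pfm.normalized

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        contexts = ["".join(rng.choice(list("ACGT"), 2)) for _ in range(100)]
        pfm = kg.build_pfm(contexts)
        assert np.allclose(pfm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_contexts_rejected(self):
        with pytest.raises(ValueError):
            kg.build_pfm([])


class TestGenomicBackground:
    def test_manual_enumeration_of_tc_sites(self):
        # "ATCA": plus-strand TC at (2,3) -> -2 base = A; no GA on plus, so
        # no minus-strand TC sites. Composition is pure A.
        genome = kg.GenomeModel(
            names=["c"], lengths={"c": 4}, sequence={"c": "ATCA"}
        )
        comp = kg.genomic_background(genome, offset=-2, condition={-1: "T"})
        assert np.allclose(comp, [1.0, 0.0, 0.0, 0.0])

    def test_both_strands_counted(self):
        # "GTCAC": plus TC at (2,3), -2 = G; minus strand: GA? none.
        # "TGAC": GA on plus at (2,3) = minus-strand TC; mutated C at plus
        # pos 2, -2 = complement(plus pos 4 = C) = G
        genome = kg.GenomeModel(
            names=["c"], lengths={"c": 4}, sequence={"c": "TGAC"}
        )
        comp = kg.genomic_background(genome, offset=-2, condition={-1: "T"})
        assert np.allclose(comp, [0.0, 0.0, 1.0, 0.0])

    def test_no_matching_sites_is_error(self):
        genome = kg.GenomeModel(
            names=["c"], lengths={"c": 8}, sequence={"c": "TTTTTTTT"}
        )
        with pytest.raises(ValueError, match="no sites"):
            kg.genomic_background(genome, offset=-2, condition={-1: "T"})

    def test_uniform_sequence_gives_uniform_composition(self, small_genome):
        comp = kg.genomic_background(small_genome, offset=-2, condition={-1: "T"})
        # GC 0.38 genome: A and T each (1-0.38)/2 = 0.31, C and G 0.19
        assert np.allclose(comp, [0.31, 0.19, 0.19, 0.31], atol=0.01)


class TestSWSimilarity:
    def test_identical_two_column_motifs_reach_maximum(self):
        pfm = kg.PRESET_PFMS["APOBEC3A"]
        assert kg.sw_similarity(pfm, pfm) == pytest.approx(4.0)

    def test_disjoint_point_masses_score_zero(self):
        a = ContextPFM((-1,), np.array([[1.0, 0.0, 0.0, 0.0]]))
        b = ContextPFM((-1,), np.array([[0.0, 1.0, 0.0, 0.0]]))
        assert kg.sw_similarity(a, b) == pytest.approx(0.0)

    def test_direct_formula_evaluation(self):
        a = ContextPFM((-1,), np.array([[0.03, 0.03, 0.03, 0.91]]))
        b = ContextPFM((-1,), np.array([[0.25, 0.25, 0.25, 0.25]]))
        assert kg.sw_similarity(a, b) == pytest.approx(1.4192)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = ContextPFM((-2, -1), rng.dirichlet(np.ones(4), 2))
        b = ContextPFM((-2, -1), rng.dirichlet(np.ones(4), 2))
        s = kg.sw_similarity(a, b)
        assert s == pytest.approx(kg.sw_similarity(b, a))
        assert 0.0 <= s <= 4.0
        assert kg.sw_similarity(a, a) == pytest.approx(4.0)

    def test_mismatched_positions_rejected(self):
        a = ContextPFM((-2, -1), np.full((2, 4), 0.25))
        b = ContextPFM((-1,), np.full((1, 4), 0.25))
        with pytest.raises(ValueError):
            kg.sw_similarity(a, b)


class TestSWPvalue:
    def test_self_comparison_attains_minimal_pvalue(self):
        pfm = kg.PRESET_PFMS["APOBEC3A"]
        res = kg.sw_pvalue(pfm, pfm, np.full(4, 0.25), n_perm=200, seed=1)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.score == pytest.approx(4.0)

    def test_zero_permutations_rejected(self):
        pfm = kg.PRESET_PFMS["AID"]
        with pytest.raises(ValueError):
            kg.sw_pvalue(pfm, pfm, np.full(4, 0.25), n_perm=0)

    def test_null_calibration_pvalues_uniform(self):
        # when the query motif is itself a draw from the permutation null,
        # p-values over repeated draws are uniform
        bg = np.full(4, 0.25)
        target = kg.PRESET_PFMS["APOBEC3B"]
        rng = np.random.default_rng(2)
        pvals = []
        for i in range(150):
            query = _draw_null_pfm(bg, target.positions, rng)
            pvals.append(
                kg.sw_pvalue(query, target, bg, n_perm=99, seed=1000 + i).p_value
            )
        ks = stats.kstest(pvals, "uniform").pvalue
        assert ks > 0.01


class TestPFMIO:
    def test_write_read_round_trip(self, tmp_path):
        pfm = kg.PRESET_PFMS["APOBEC3B"]
        path = tmp_path / "a3b.pfm"
        kg.write_pfm(pfm, path)
        back = kg.read_pfm(path)
        assert back.positions == pfm.positions
        assert np.allclose(back.matrix, pfm.matrix, atol=1e-6)

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "bad.pfm"
        path.write_text("# positions: -2 -1\nA 0.5 0.5\nC 0.5 0.5\n")
        with pytest.raises(ValueError):
            kg.read_pfm(path)


class TestPresetLibrary:
    def test_each_preset_matches_itself_best(self):
        for name, pfm in kg.PRESET_PFMS.items():
            match, scores = kg.best_match(pfm)
            assert match == name
            assert scores[name] == pytest.approx(4.0)

    def test_a3a_minus2_weights(self):
        col = kg.PRESET_PFMS["APOBEC3A"].column(-2)
        assert np.allclose(col, [0.25, 0.26, 0.07, 0.42])
        assert kg.PRESET_PFMS["APOBEC3A"].base_fraction(-1, "T") == pytest.approx(0.91)
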