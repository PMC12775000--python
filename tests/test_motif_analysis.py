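import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allelescan import (
    PositionFrequencyMatrix,
    binding_report,
    extract_windows,
    gen_motif_and_variant,
    motif_pvalue,
    pfm_to_pwm,
    pvalue_fold_change,
    scan_allele,
    score_distribution,
    score_kmer,
)
from allelescan.motif_analysis import count_placements
from allelescan.synthetic_data import SimulationConfig
from allelescan.types import ValidationError, VariantRecord, reverse_complement
from conftest import random_count_pfm
from oracles import (
    best_hit_score_bruteforce,
    enumerate_exact_scores,
    enumerate_score_distribution,
)


class TestPfmToPwm:
    def test_uniform_counts_give_zero_log_odds(self):
        pfm = PositionFrequencyMatrix("u", np.ones((4, 5)))
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)

    def test_zero_count_without_pseudocount_errors(self):
        pfm = PositionFrequencyMatrix("z", np.array([[1.0], [0.0], [0.0], [0.0]]))
        with pytest.raises(ValidationError, match="position 0"):
            pfm_to_pwm(pfm, pseudocount=0.0)

    def test_pseudocount_hand_computation(self):
        # (1 + 0.25) / (1 + 4*0.25) = 0.625; log2(0.625/0.25) = log2(2.5)
        pfm = PositionFrequencyMatrix("z", np.array([[1.0], [0.0], [0.0], [0.0]]))
        pwm = pfm_to_pwm(pfm, pseudocount=0.25)
        assert pwm.log_odds[0, 0] == pytest.approx(math.log2(2.5), abs=1e-12)

    def test_frequency_matrix_passthrough(self):
        freqs = np.array([[0.4, 0.1], [0.3, 0.2], [0.2, 0.3], [0.1, 0.4]])
        pfm = PositionFrequencyMatrix("f", freqs, is_frequency=True)
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        np.testing.assert_allclose(pwm.log_odds, np.log2(freqs / 0.25), atol=1e-12)


class TestScoreKmer:
    def test_uniform_pwm_scores_zero(self, uniform_pwm):
        assert score_kmer(uniform_pwm, "ACGTACGTACG") == pytest.approx(0.0)

    def test_additive_two_position_example(self, two_level_pwm):
        assert score_kmer(two_level_pwm, "AG") == pytest.approx(3.0)
        assert score_kmer(two_level_pwm, "CG") == pytest.approx(3.0)

    def test_length_mismatch_and_ambiguous_base(self, two_level_pwm):
        with pytest.raises(ValidationError, match="length"):
            score_kmer(two_level_pwm, "AGG")
        with pytest.raises(ValidationError, match="N"):
            score_kmer(two_level_pwm, "AN")


class TestExtractWindows:
    def test_central_variant(self):
        contig = "A" * 50 + "C" + "G" * 50
        v = VariantRecord("c", 51, "v", "C", "T")
        pair = extract_windows({"c": contig}, v, flank=25)
        assert len(pair.ref_window) == 51
        assert pair.variant_offset == 25
        assert pair.ref_window[25] == "C" and pair.alt_window[25] == "T"
        # windows differ only at the center
        diffs = [i for i, (a, b) in enumerate(zip(pair.ref_window, pair.alt_window)) if a != b]
        assert diffs == [25]

    def test_reference_mismatch_quotes_bases(self):
        contig = "A" * 50 + "G" + "G" * 50
        v = VariantRecord("c", 51, "v", "C", "T")
        with pytest.raises(ValidationError, match="found 'G', expected 'C'"):
            extract_windows({"c": contig}, v, flank=25)

    def test_out_of_bounds(self):
        v = VariantRecord("c", 10, "v", "A", "T")
        with pytest.raises(ValidationError, match="exceeds"):
            extract_windows({"c": "A" * 101}, v, flank=25)


class TestScanAllele:
    def test_placement_count_central_variant(self):
        # 51 bp window, 11 bp motif, central variant: offsets 15..25, 2 strands
        assert count_placements(11, 51, 25) == 22

    def test_placement_count_edge_variant(self):
        assert count_placements(11, 11, 0) == 2

    def test_palindromic_tie_prefers_plus_strand(self, uniform_pwm):
        hit = scan_allele(uniform_pwm, "ACGT" * 12 + "ACG", 25)
        assert hit.strand == "+"
        assert hit.offset == 15  # smallest covering offset

    def test_window_shorter_than_motif_errors(self, uniform_pwm):
        with pytest.raises(ValidationError):
            scan_allele(uniform_pwm, "ACGTACGTAC", 5)

    def test_matches_bruteforce_best(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pwm = pfm_to_pwm(random_count_pfm(rng, 7), pseudocount=0.0)
            window = "".join(rng.choice(list("ACGT"), size=31))
            off = int(rng.integers(0, 31))
            hit = scan_allele(pwm, window, off)
            expected = best_hit_score_bruteforce(pwm.log_odds, window, off)
            assert hit.score == pytest.approx(expected, abs=1e-12)

    def test_efficiency_is_two_to_score(self):
        rng = np.random.default_rng(3)
        pwm = pfm_to_pwm(random_count_pfm(rng, 5), pseudocount=0.0)
        hit = scan_allele(pwm, "ACGTTGCAAC", 4)
        assert hit.efficiency == pytest.approx(2.0 ** hit.score, rel=1e-12)


class TestBindingReport:
    def test_uniform_pwm_fold_change_one(self, uniform_pwm):
        cfg = SimulationConfig(seed=5)
        _, pair, _ = gen_motif_and_variant(cfg)
        rep = binding_report(uniform_pwm, pair)
        assert rep.efficiency_fold_change == pytest.approx(1.0)
        assert rep.favored_allele == "none"

    def test_planted_disruption_recovers_ratio(self):
        # alt allele drops the informative position from 0.8 to 0.1:
        # coincident placements give fold change 0.8/0.1 = 8
        cfg = SimulationConfig(seed=5, consensus_freq=0.8, disrupted_freq=0.1)
        pfm, pair, expected = gen_motif_and_variant(cfg)
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        rep = binding_report(pwm, pair)
        assert rep.ref_hit.offset == rep.alt_hit.offset
        assert 1.0 / rep.efficiency_fold_change == pytest.approx(8.0, rel=1e-12)
        assert -rep.log2_fold_change == pytest.approx(expected, abs=1e-9)
        assert rep.favored_allele == "ref"

    def test_allele_swap_inverts_fold_change(self):
        cfg = SimulationConfig(seed=9)
        pfm, pair, _ = gen_motif_and_variant(cfg)
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        fwd = binding_report(pwm, pair).efficiency_fold_change
        rev = binding_report(pwm, pair.swapped()).efficiency_fold_change
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_coincident_placement_identity(self):
        # same strand/offset best hits: log2 fold equals the log-odds
        # difference at the aligned position
        cfg = SimulationConfig(seed=5)
        pfm, pair, _ = gen_motif_and_variant(cfg)
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        rep = binding_report(pwm, pair)
        assert rep.ref_hit.strand == rep.alt_hit.strand == "+"
        assert rep.ref_hit.offset == rep.alt_hit.offset
        j = pair.variant_offset - rep.ref_hit.offset
        from allelescan.types import BASE_INDEX

        delta = (
            pwm.log_odds[BASE_INDEX[pair.variant.alt], j]
            - pwm.log_odds[BASE_INDEX[pair.variant.ref], j]
        )
        assert rep.log2_fold_change == pytest.approx(delta, abs=1e-9)


class TestScoreDistribution:
    def test_uniform_pwm_point_mass_at_zero(self, uniform_pwm):
        dist = score_distribution(uniform_pwm)
        assert len(dist.support) == 1
        assert dist.support[0] == pytest.approx(0.0)
        assert dist.mass[0] == pytest.approx(1.0)

    def test_single_position_enumeration(self):
        from allelescan.motif_analysis import PositionWeightMatrix

        pwm = PositionWeightMatrix(
            "L1", np.array([[2.0], [-1.0], [-1.0], [-1.0]]), np.full(4, 0.25)
        )
        dist = score_distribution(pwm)
        np.testing.assert_allclose(sorted(dist.support), [-1.0, 2.0])
        np.testing.assert_allclose(dist.mass[np.argsort(dist.support)], [0.75, 0.25])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        for L in (2, 4, 6):
            pwm = pfm_to_pwm(random_count_pfm(rng, L), pseudocount=0.0)
            dist = score_distribution(pwm, grid_step=0.001)
            support, mass = enumerate_score_distribution(
                pwm.log_odds, pwm.background, 0.001
            )
            got = {int(round(s / 0.001)): m for s, m in zip(dist.support, dist.mass)}
            tv = 0.5 * sum(
                abs(got.get(int(s), 0.0) - m) for s, m in zip(support, mass)
            ) + 0.5 * sum(m for g, m in got.items() if g not in set(support.tolist()))
            assert tv < 1e-9

    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(4)
        pwm = pfm_to_pwm(random_count_pfm(rng, 9), pseudocount=0.0)
        dist = score_distribution(pwm)
        assert dist.mass.sum() == pytest.approx(1.0, abs=1e-12)


class TestMotifPvalue:
    def test_minimum_support_gives_one(self):
        rng = np.random.default_rng(2)
        pwm = pfm_to_pwm(random_count_pfm(rng, 6), pseudocount=0.0)
        dist = score_distribution(pwm)
        assert motif_pvalue(dist, pwm.min_score) == pytest.approx(1.0)

    def test_single_position_tail(self):
        from allelescan.motif_analysis import PositionWeightMatrix

        pwm = PositionWeightMatrix(
            "L1", np.array([[2.0], [-1.0], [-1.0], [-1.0]]), np.full(4, 0.25)
        )
        dist = score_distribution(pwm)
        assert motif_pvalue(dist, 2.0) == pytest.approx(0.25)

    def test_two_position_tail(self, two_level_pwm):
        dist = score_distribution(two_level_pwm)
        # P(pos1 in {A,C}) * P(pos2 = G) = 0.5 * 0.25
        assert motif_pvalue(dist, 3.0) == pytest.approx(0.125)

    def test_non_increasing_in_score(self):
        rng = np.random.default_rng(8)
        pwm = pfm_to_pwm(random_count_pfm(rng, 6), pseudocount=0.0)
        dist = score_distribution(pwm)
        grid = np.linspace(pwm.min_score - 1, pwm.max_score + 1, 200)
        ps = [motif_pvalue(dist, s) for s in grid]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_conservative_versus_exact(self):
        # flooring to the grid must never yield a p-value below the exact
        # tail probability from full enumeration
        rng = np.random.default_rng(17)
        for L in (3, 5, 7):
            pwm = pfm_to_pwm(random_count_pfm(rng, L), pseudocount=0.0)
            dist = score_distribution(pwm, grid_step=0.001)
            scores = enumerate_exact_scores(pwm.log_odds)
            for q in rng.choice(scores, size=25, replace=False):
                exact = float((scores >= q - 1e-12).mean())
                assert motif_pvalue(dist, q) >= exact - 1e-12


class TestPvalueFoldChange:
    def test_identical_alleles_in_uninformative_motif(self, uniform_pwm):
        cfg = SimulationConfig(seed=5)
        _, pair, _ = gen_motif_and_variant(cfg)
        ratio, favored = pvalue_fold_change(uniform_pwm, pair)
        assert ratio == pytest.approx(1.0)
        assert favored == "none"

    def test_disruptive_snv_favors_consensus(self):
        cfg = SimulationConfig(seed=5)
        pfm, pair, _ = gen_motif_and_variant(cfg)
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        ratio, favored = pvalue_fold_change(pwm, pair)
        assert ratio > 1.0
        assert favored == "ref"

    def test_ratio_matches_bruteforce_enumeration(self):
        cfg = SimulationConfig(seed=13, motif_length=6, informative_position=3, flank=10)
        pfm, pair, _ = gen_motif_and_variant(cfg)
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        ratio, _ = pvalue_fold_change(pwm, pair)

        eps = 0.001
        ref_best = best_hit_score_bruteforce(pwm.log_odds, pair.ref_window, pair.variant_offset)
        alt_best = best_hit_score_bruteforce(pwm.log_odds, pair.alt_window, pair.variant_offset)
        # oracle tail probabilities with the same grid convention
        support, mass = enumerate_score_distribution(pwm.log_odds, pwm.background, eps)
        L = pwm.length

        def oracle_p(q):
            thr = math.floor(q / eps) - (L - 1)
            return float(mass[support >= thr - 0.5].sum())

        p_ref, p_alt = oracle_p(ref_best), oracle_p(alt_best)
        expected = max(p_ref, p_alt) / min(p_ref, p_alt)
        assert ratio == pytest.approx(expected, rel=1e-9)


class TestStrandSymmetry:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_reverse_complement_scan_invariance(self, seed):
        """Scanning a window and its reverse complement finds the same
        best score, at the mirrored offset."""
        rng = np.random.default_rng(seed)
        pwm = pfm_to_pwm(random_count_pfm(rng, 5), pseudocount=0.0)
        window = "".join(rng.choice(list("ACGT"), size=21))
        off = int(rng.integers(0, 21))
        fwd = scan_allele(pwm, window, off)
        rev = scan_allele(pwm, reverse_complement(window), len(window) - 1 - off)
        assert fwd.score == pytest.approx(rev.score, abs=1e-12)
        assert rev.offset == len(window) - pwm.length - fwd.offset

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_fold_change_inversion_property(self, seed):
        cfg = SimulationConfig(seed=seed)
        pfm, pair, _ = gen_motif_and_variant(cfg)
        pwm = pfm_to_pwm(pfm, pseudocount=0.0)
        fwd = binding_report(pwm, pair).efficiency_fold_change
        rev = binding_report(pwm, pair.swapped()).efficiency_fold_change
        assert fwd * rev == pytest.approx(1.0, rel=1e-9)
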