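"""PWM construction, window scoring, region scanning, Gibbs sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aluhsf.motif import (
    MotifScanConfig,
    build_pwm,
    consensus_string,
    default_hsf_pwm,
    gibbs_sample_motif,
    majority_consensus,
    revcomp,
    scan_region,
    score_window,
)

from .oracles import naive_scan


class TestBuildPwm:
    def test_identical_sites_give_degenerate_frequencies(self):
        pwm = build_pwm(["ACGT", "ACGT"], pseudocount=0.0)
        assert np.allclose(pwm.frequencies[:, 0], [1.0, 0.0, 0.0, 0.0])
        assert np.allclose(pwm.frequencies.sum(axis=0), 1.0)

    def test_single_site_pseudocount_arithmetic(self):
        # (1+1)/(1+4) for the observed base, 1/5 for the others
        pwm = build_pwm(["A"], pseudocount=1.0)
        assert pwm.frequencies[0, 0] == pytest.approx(0.4)
        assert np.allclose(pwm.frequencies[1:, 0], 0.2)

    def test_column_tally(self):
        pwm = build_pwm(["AC", "AG"], pseudocount=0.0)
        assert pwm.frequencies[1, 1] == pytest.approx(0.5)  # C
        assert pwm.frequencies[2, 1] == pytest.approx(0.5)  # G

    @pytest.mark.parametrize(
        "sites", [[], ["AC", "ACG"], ["AN"]], ids=["empty", "ragged", "ambiguous"]
    )
    def test_invalid_site_sets_rejected(self, sites):
        with pytest.raises(ValueError):
            build_pwm(sites)


class TestScoreWindow:
    def test_unique_site_scores_two_bits_per_column(self):
        site = "GCAGAAAGCTCCG"
        pwm = build_pwm([site], pseudocount=0.0)
        assert score_window(pwm, site) == pytest.approx(13 * math.log2(4))

    def test_hand_summed_score(self):
        pwm = build_pwm(["AC", "AG"], pseudocount=0.0)
        # log2(1/.25) + log2(.5/.25)
        assert score_window(pwm, "AC") == pytest.approx(3.0)

    def test_zero_frequency_base_scores_minus_infinity(self):
        pwm = build_pwm(["AC", "AG"], pseudocount=0.0)
        assert score_window(pwm, "TC") == float("-inf")

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            score_window(default_hsf_pwm(), "ACGT")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_no_word_beats_columnwise_maxima(self, seed):
        rng = np.random.default_rng(seed)
        pwm = default_hsf_pwm()
        word = "".join(rng.choice(list("ACGT"), size=pwm.width))
        assert score_window(pwm, word) <= pwm.max_score + 1e-12


class TestScanRegion:
    def test_sequence_shorter_than_width_yields_nothing(self):
        assert scan_region(default_hsf_pwm(), "A" * 12) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        pwm = default_hsf_pwm()
        seq = "".join(rng.choice(list("ACGT"), size=400))
        # low threshold so both hit and near-hit bookkeeping is exercised
        config = MotifScanConfig(threshold=4.0)
        got = [(h.start, h.strand, h.score, h.matched_word)
               for h in scan_region(pwm, seq, config)]
        expected = naive_scan(pwm, seq, 4.0)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[0] == e[0] and g[1] == e[1] and g[3] == e[3]
            assert g[2] == pytest.approx(e[2], abs=1e-9)

    def test_reverse_complement_planting_found_on_minus_strand(self):
        pwm = default_hsf_pwm()
        top = "ACAGAAAGCTCCG"
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        seq = seq[:50] + revcomp(top) + seq[63:]
        hits = [h for h in scan_region(pwm, seq) if h.strand == "-"]
        assert any(h.start == 50 and h.matched_word == top for h in hits)

    def test_strand_symmetry(self):
        """Minus-strand scan equals plus-strand scan of the revcomp, mirrored."""
        pwm = default_hsf_pwm()
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        config = MotifScanConfig(threshold=3.0)
        direct = {(h.start, h.strand, h.matched_word) for h in scan_region(pwm, seq, config)}
        mirrored = {
            (len(seq) - h.end, "-" if h.strand == "+" else "+", h.matched_word)
            for h in scan_region(pwm, revcomp(seq), config)
        }
        assert direct == mirrored

    def test_ambiguous_bases_skipped_by_default(self):
        pwm = default_hsf_pwm()
        seq = "ACAGAAAGCTCCG".replace("T", "N")
        assert scan_region(pwm, seq, MotifScanConfig(threshold=-100.0)) == []


class TestConsensusString:
    def test_dominant_column_renders_letter(self):
        pwm = build_pwm(["A"] * 9 + ["C"], pseudocount=0.0)
        assert consensus_string(pwm, 0.5) == "A"

    def test_sub_cutoff_column_renders_n(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
        assert consensus_string(pwm, 0.5) == "n"

    def test_default_model_prints_degenerate_13mer(self):
        s = consensus_string(default_hsf_pwm())
        assert len(s) == 13
        assert s[0] == "n"
        assert s == "nCAGAAAGCTCCG"


class TestGibbsSampler:
    @staticmethod
    def _planted_sequences(rng, n=10, length=120, motif="GCAGAAAGCTCCG"):
        seqs, offsets = [], []
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            o = int(rng.integers(0, length - len(motif) + 1))
            seqs.append(seq[:o] + motif + seq[o + len(motif):])
            offsets.append(o)
        return seqs, offsets

    def test_recovers_exactly_planted_motif(self):
        rng = np.random.default_rng(42)
        motif = "GCAGAAAGCTCCG"
        seqs, offsets = self._planted_sequences(rng, n=12, length=150, motif=motif)
        pwm, found = gibbs_sample_motif(seqs, 13, n_iterations=300, n_restarts=8, seed=9)
        assert majority_consensus(pwm) == motif
        exact = sum(1 for f, o in zip(found, offsets) if f == o)
        assert exact >= 0.95 * len(seqs)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        seqs, _ = self._planted_sequences(rng)
        a = gibbs_sample_motif(seqs, 13, n_iterations=100, n_restarts=3, seed=4)
        b = gibbs_sample_motif(seqs, 13, n_iterations=100, n_restarts=3, seed=4)
        assert a[1] == b[1]
        assert np.array_equal(a[0].counts, b[0].counts)

    def test_degenerate_single_base_input_completes(self):
        seqs = ["A" * 60] * 8
        pwm, _ = gibbs_sample_motif(seqs, 13, n_iterations=50, n_restarts=2, seed=1)
        rng = np.random.default_rng(3)
        planted, _ = self._planted_sequences(rng, n=8, length=60)
        strong, _ = gibbs_sample_motif(planted, 13, n_iterations=200, n_restarts=4, seed=1)
        assert pwm.information_content() <= strong.information_content() + 1e-9

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            gibbs_sample_motif(["ACGTACGTACGT", "A" * 20], 13)
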