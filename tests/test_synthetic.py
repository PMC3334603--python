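"""Synthetic-data generator: planting, mutation, determinism, truth table."""

import dataclasses

import numpy as np
import pytest

from aluhsf.motif import MOTIF_WIDTH, default_hsf_pwm, encode, revcomp
from aluhsf.synthetic import (
    TOY_ALU_CONSENSUS,
    ConfigError,
    SyntheticConfig,
    generate_dataset,
    mutate_sequence,
    plant_motif,
    validate_dataset,
)


class TestPlantMotif:
    MOTIF = "GCAGAAAGCTCCG"

    def test_boundary_placement_at_position_one(self):
        out = plant_motif("A" * 40, self.MOTIF, 1)
        assert out.startswith(self.MOTIF)
        assert len(out) == 40

    def test_read_back_at_221(self):
        out = plant_motif(TOY_ALU_CONSENSUS, self.MOTIF, 221)
        assert out[220:233] == self.MOTIF

    def test_reverse_plant_mirrors_under_revcomp(self):
        out = plant_motif(TOY_ALU_CONSENSUS, self.MOTIF, 91, orientation="reverse")
        mirrored = revcomp(out)
        offset = len(out) - 91 - 12  # 0-based start on the opposite strand
        assert mirrored[offset : offset + 13] == self.MOTIF

    @pytest.mark.parametrize("pos", [0, 289, 1000])
    def test_out_of_range_position_rejected(self, pos):
        with pytest.raises(ValueError):
            plant_motif(TOY_ALU_CONSENSUS, self.MOTIF, pos)


class TestMutateSequence:
    def test_zero_rates_identity(self):
        seq = TOY_ALU_CONSENSUS
        assert mutate_sequence(seq, 0.0, 0.0, seed=1) == seq

    def test_forced_indel_changes_odd_length(self):
        assert len(mutate_sequence("ACGTA", 0.0, 1.0, seed=2)) != 5

    def test_substitution_count_matches_binomial_expectation(self):
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=10000))
        subs = []
        for seed in range(100):
            out = mutate_sequence(seq, 0.05, 0.0, seed=seed)
            subs.append(sum(a != b for a, b in zip(seq, out)))
        expected = 0.05 * 10000
        se = np.sqrt(10000 * 0.05 * 0.95) / np.sqrt(100)
        assert abs(np.mean(subs) - expected) < 3 * se

    def test_protected_window_untouched(self):
        seq = TOY_ALU_CONSENSUS
        out = mutate_sequence(seq, 0.5, 0.0, seed=3, protect=[(100, 113)])
        assert out[100:113] == seq[100:113]

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            mutate_sequence("ACGT", 1.5, 0.0, seed=0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"motif_plant_prob_sense": 1.2},
            {"alu_mutation_rate": -0.1},
            {"alu_consensus": "ACGT"},
            {"plant_positions": {"sense": (295,), "antisense": (91,)}},
            {"gene_length_kb": (5.0, 2.0)},
        ],
        ids=["prob>1", "rate<0", "short-consensus", "position-overflow", "bad-range"],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SyntheticConfig(**kwargs).validate()


class TestGenerateDataset:
    def test_zero_alu_rate_gives_empty_tables(self):
        cfg = SyntheticConfig(
            seed=0,
            n_genes_per_class={"up": 3, "down": 3, "unchanged": 0, "random": 0},
            alu_rate_per_kb={c: 0.0 for c in ("up", "down", "unchanged", "random")},
        )
        ds = generate_dataset(cfg)
        assert ds.alus == [] and len(ds.truth) == 0
        assert len(ds.genes) == 6

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(
            seed=7, n_genes_per_class={"up": 5, "down": 5, "unchanged": 0, "random": 0}
        )
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert a.genome == b.genome
        assert a.truth.equals(b.truth)
        assert a.signals.equals(b.signals)

    def test_certain_antisense_planting_readable_from_genome(self):
        """With plant prob 1 at position 91 and no mutation, every antisense
        Alu carries the exact 13-mer at consensus offset 91."""
        cfg = SyntheticConfig(
            seed=3,
            n_genes_per_class={"up": 0, "down": 8, "unchanged": 0, "random": 0},
            alu_mutation_rate=0.0,
            indel_rate=0.0,
            motif_plant_prob_sense=0.0,
            motif_plant_prob_antisense=1.0,
            plant_positions={"sense": (175,), "antisense": (91,)},
        )
        ds = generate_dataset(cfg)
        antisense = [a for a in ds.alus if a.orientation_class == "antisense"]
        assert len(antisense) > 0
        assert len(ds.truth) == len(antisense)
        assert set(ds.truth.consensus_position) == {91}
        for _, row in ds.truth.iterrows():
            word = ds.genome[row.chrom][row.start : row.end]
            if row.strand == "-":
                word = revcomp(word)
            assert word == row.motif_word
            # the copy equals the consensus outside the planted window
            alu = next(a for a in ds.alus if a.alu_id == row.alu_id)
            copy = ds.genome[alu.chrom][alu.start : alu.end]
            if alu.strand == "-":
                copy = revcomp(copy)
            assert copy[90:103] == row.motif_word

    def test_truth_table_retrievability_invariant(self, small_dataset):
        validate_dataset(small_dataset)

    def test_alu_density_recovers_configured_rate(self):
        cfg = SyntheticConfig(
            seed=5,
            n_genes_per_class={"up": 0, "down": 220, "unchanged": 0, "random": 0},
            alu_rate_per_kb={"up": 0, "down": 0.5, "unchanged": 0, "random": 0},
        )
        ds = generate_dataset(cfg)
        total_kb = sum(r.length for r in ds.regions) / 1000.0
        rate = len(ds.alus) / total_kb
        se = np.sqrt(0.5 * total_kb) / total_kb  # Poisson SE of the rate
        assert abs(rate - 0.5) < 3 * se

    def test_consensus_has_no_motif_like_window(self):
        """Unplanted copies must be silent under the default model: every
        window of the bundled consensus, on both strands, stays well below
        the scanning threshold."""
        pwm = default_hsf_pwm()
        best = -np.inf
        for seq in (TOY_ALU_CONSENSUS, revcomp(TOY_ALU_CONSENSUS)):
            codes = encode(seq)
            for i in range(len(codes) - MOTIF_WIDTH + 1):
                s = pwm.log_odds[codes[i : i + MOTIF_WIDTH], np.arange(MOTIF_WIDTH)].sum()
                best = max(best, s)
        assert best < 1.0

    def test_signals_sit_at_configured_offset(self, small_dataset):
        """Each detected signal's planted site lies one offset away, on the
        antisense transcript's upstream side."""
        ds = small_dataset
        gap = int(ds.config.antisense_signal_offset_kb * 1000)
        truth = ds.truth
        planted = ds.signals[ds.signals.detection_p < 0.05]
        assert len(planted) > 0
        for _, sig in planted.iterrows():
            t = truth[(truth.gene_id == sig.gene_id) & (truth.region_kind == "genic")]
            gaps = []
            for _, row in t.iterrows():
                gaps.append(max(row.start - sig.end, sig.start - row.end, 0))
            assert gap in gaps
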