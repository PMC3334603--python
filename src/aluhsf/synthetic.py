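"""Seeded synthetic datasets with planted Alu-internal HSF sites.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without genome downloads:

* one contig per gene (5-kb pad, genic body, 5-kb pad), eliminating
  inter-gene interval ambiguity;
* per-class Alu insertion counts are Poisson draws at a per-kilobase rate,
  with down-regulated genes enriched over up-regulated ones;
* each inserted Alu is a mutated copy of a bundled ~300-base toy consensus
  (substitutions and indels model subfamily divergence);
* the 13-bp HSF motif is planted at orientation-specific consensus positions
  — 221 and 175 for sense Alus, 221 and 91 for antisense Alus — with a
  higher planting probability in antisense copies;
* for down-regulated genes, a 100-base antisense probe signal is emitted a
  configurable distance (default 2 kb) downstream — in the antisense
  transcript's direction — of each planted genic antisense-Alu site.

Every planted motif instance is recorded in a truth table with its genomic
coordinates, orientation and consensus position.  Identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import AluElement, GeneModel, RegionSpec, extract_regions
from .motif import ALPHABET, MOTIF_WIDTH, HSF_CONSENSUS_CORE, revcomp


def _make_toy_consensus() -> str:
    """Bundled 300-base GC-rich toy Alu consensus.

    Not a RepBase sequence: a fixed pseudo-random GC-rich body carrying a
    literal B-box-like RNA pol III internal element and a 3' poly-A tail,
    which is all the positional-mapping machinery needs.  Two properties are
    built in.  First, no window on either strand comes within four
    substitutions of the 13-bp HSF motif, so unplanted copies carry no
    motif-like words.  Second, at the canonical site positions (221, 175,
    91) the consensus shares five scattered bases with the motif core —
    echoing the real situation, where the heat shock element derives from
    Alu sequence itself — which anchors local alignments of planted copies
    in the correct register while leaving the windows far below the score
    threshold.
    """
    rng = np.random.default_rng(2015)
    body = list("".join(rng.choice(list("ACGT"), size=300, p=[0.2, 0.3, 0.3, 0.2])))
    body[6:15] = "TGGCTCACG"                       # A-box-like 5' element
    body[72:81] = "GTTCGAGAC"                      # B-box-like internal element
    body[290:] = "A" * 10                          # poly-A tail
    core = "n" + HSF_CONSENSUS_CORE
    for p in (221, 175, 91):                       # motif-compatible anchors
        for j in (1, 4, 7, 10, 12):
            body[p - 1 + j] = core[j]
    return "".join(body)


TOY_ALU_CONSENSUS = _make_toy_consensus()

#: Degenerate 13-mer planted by default; 'n' is resolved per instance.
DEFAULT_PLANT_MOTIF = "n" + HSF_CONSENSUS_CORE


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Defaults encode the study conditions the analysis targets: genic Alu
    enrichment in down-regulated genes (down:up rate ratio 1.5), per-Alu HSF
    site fractions of ~4% (sense) and ~21% (antisense), plant positions
    221/175 (sense) and 221/91 (antisense) on the consensus, ~5% per-base
    Alu divergence, and antisense probe signals 2 kb from planted sites.
    """

    seed: int = 0
    n_genes_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"up": 60, "down": 60, "unchanged": 60, "random": 60}
    )
    gene_length_kb: tuple[float, float] = (10.0, 30.0)
    upstream_len: int = 5000
    alu_rate_per_kb: Mapping[str, float] = field(
        default_factory=lambda: {"up": 0.4, "down": 0.6, "unchanged": 0.3, "random": 0.3}
    )
    alu_consensus: str = TOY_ALU_CONSENSUS
    alu_mutation_rate: float = 0.05
    indel_rate: float = 0.005
    motif_plant_prob_sense: float = 0.04
    motif_plant_prob_antisense: float = 0.21
    plant_positions: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {"sense": (221, 175), "antisense": (221, 91)}
    )
    motif: str = DEFAULT_PLANT_MOTIF
    background_gc: float = 0.41
    antisense_signal_offset_kb: float = 2.0
    signal_len: int = 100
    noise_signal_prob: float = 0.1
    protect_planted: bool = True
    subfamily: str = "AluSy"

    def validate(self) -> None:
        for name, p in (
            ("motif_plant_prob_sense", self.motif_plant_prob_sense),
            ("motif_plant_prob_antisense", self.motif_plant_prob_antisense),
            ("background_gc", self.background_gc),
            ("noise_signal_prob", self.noise_signal_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name, r in (
            ("alu_mutation_rate", self.alu_mutation_rate),
            ("indel_rate", self.indel_rate),
        ):
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {r}")
        if any(v < 0 for v in self.alu_rate_per_kb.values()):
            raise ConfigError("alu_rate_per_kb values must be >= 0")
        if len(self.alu_consensus) < MOTIF_WIDTH:
            raise ConfigError("alu_consensus shorter than the 13-bp motif")
        if len(self.motif) != MOTIF_WIDTH:
            raise ConfigError("planted motif must be 13 bases")
        hi = len(self.alu_consensus) - (MOTIF_WIDTH - 1)
        for orient, positions in self.plant_positions.items():
            for p in positions:
                if not 1 <= p <= hi:
                    raise ConfigError(
                        f"plant position {p} ({orient}) outside [1, {hi}]"
                    )
        lo, hi_kb = self.gene_length_kb
        if not 0 < lo <= hi_kb:
            raise ConfigError("gene_length_kb must be a positive (low, high) range")
        if self.upstream_len <= 0 or self.signal_len <= 0:
            raise ConfigError("upstream_len and signal_len must be positive")


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus the planted-motif truth table."""

    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    regions: list[RegionSpec]
    alus: list[AluElement]  # hosted: host_gene / orientation / region_kind set
    signals: pd.DataFrame
    truth: pd.DataFrame

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def to_files(self, outdir) -> dict[str, str]:
        from . import io as _io

        return _io.write_dataset(self, outdir)


def plant_motif(
    alu_seq: str, motif: str, consensus_position: int, orientation: str = "forward"
) -> str:
    """Overwrite 13 bases of ``alu_seq`` with the motif at a 1-based position.

    ``orientation="reverse"`` plants the reverse complement.  The position is
    in the coordinate frame of ``alu_seq`` itself (the consensus frame when
    planting into an unmutated copy).
    """
    w = len(motif)
    if not 1 <= consensus_position <= len(alu_seq) - (w - 1):
        raise ValueError(
            f"plant position {consensus_position} outside [1, {len(alu_seq) - w + 1}]"
        )
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    word = motif if orientation == "forward" else revcomp(motif)
    i = consensus_position - 1
    return alu_seq[:i] + word + alu_seq[i + w :]


def _in_windows(i: int, windows) -> bool:
    return any(s <= i < e for s, e in windows)


def _mutate_tracked(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    protect=(),
) -> tuple[str, dict[int, int]]:
    """Mutate a sequence, returning it with the new starts of protected windows.

    Per base: an indel event occurs with probability ``indel_rate`` (half
    deletions, half single-base insertions placed before the base), and an
    independent substitution with probability ``sub_rate``.  Protected
    windows are copied verbatim; indels elsewhere shift their offsets, which
    is what the returned mapping (old start -> new start) records.
    """
    bases = list(ALPHABET)
    out: list[str] = []
    new_starts: dict[int, int] = {}
    starts = {s for s, _ in protect}
    for i, base in enumerate(seq):
        if _in_windows(i, protect):
            if i in starts:
                new_starts[i] = len(out)
            out.append(base)
            continue
        if indel_rate > 0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(bases[rng.integers(4)])  # insertion before this base
        if sub_rate > 0 and rng.random() < sub_rate:
            k = (ALPHABET.index(base) + 1 + rng.integers(3)) % 4 if base in ALPHABET else rng.integers(4)
            out.append(bases[int(k)])
        else:
            out.append(base)
    return "".join(out), new_starts


def mutate_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    protect=(),
) -> str:
    """Substitution/indel mutation of a sequence (seeded).

    ``protect`` is an iterable of half-open windows exempt from mutation,
    used to keep planted motifs intact.  Expected substitution count is
    approximately ``sub_rate * len(seq)``.
    """
    for name, r in (("sub_rate", sub_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= r <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1], got {r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if indel_rate == 0 and not protect:
        # vectorised fast path for the substitution-only case
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
        hit = rng.random(len(arr)) < sub_rate
        if hit.any():
            lut = {ord(b): i for i, b in enumerate(ALPHABET)}
            codes = np.array([lut.get(c, 0) for c in arr[hit]])
            shifted = (codes + 1 + rng.integers(0, 3, size=codes.size)) % 4
            arr[hit] = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)[shifted]
        return arr.tobytes().decode()
    out, _ = _mutate_tracked(seq, sub_rate, indel_rate, rng, protect=protect)
    return out


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(ALPHABET), size=length, p=p))


def simulate_gene_table(
    config: SyntheticConfig, rng: np.random.Generator
) -> list[dict]:
    """Draw the annotation skeleton: genes, regions, per-region Alu counts.

    This is the counting layer of the generator — gene lengths, contig
    layout, and Poisson Alu counts at the per-class rate — shared by
    :func:`generate_dataset` and usable on its own when only densities
    matter and no sequence needs to be materialised.
    """
    config.validate()
    up = config.upstream_len
    lo, hi = config.gene_length_kb
    rows = []
    for cls in ("up", "down", "unchanged", "random"):
        n_genes = config.n_genes_per_class.get(cls, 0)
        rate = config.alu_rate_per_kb.get(cls, 0.0)
        for i in range(n_genes):
            gene_id = f"{cls}_{i + 1:04d}"
            gene_len = int(round(rng.uniform(lo, hi) * 1000))
            contig_len = gene_len + 2 * up
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel(gene_id, gene_id, strand, up, up + gene_len, cls)
            upstream, genic = extract_regions(gene, contig_len, up)
            rows.append(
                {
                    "gene": gene,
                    "contig_len": contig_len,
                    "regions": (upstream, genic),
                    "n_alus": {
                        r.kind: int(rng.poisson(rate * r.length / 1000.0))
                        for r in (upstream, genic)
                    },
                }
            )
    return rows


def _resolve_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        ALPHABET[int(rng.integers(4))] if c in "nN" else c.upper() for c in motif
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete seeded dataset (genome, annotations, truth).

    See the module docstring for the planted structure.  Alu copies are
    placed uniformly within their region without overlapping each other
    (placements that cannot be accommodated after 50 attempts are dropped);
    planted-motif windows are protected from mutation when
    ``config.protect_planted`` is set (the default), so positional-recovery
    checks are deterministic in expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    skeleton = simulate_gene_table(config, rng)

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    regions: list[RegionSpec] = []
    alus: list[AluElement] = []
    truth_rows: list[dict] = []
    signal_rows: list[dict] = []

    plant_prob = {
        "sense": config.motif_plant_prob_sense,
        "antisense": config.motif_plant_prob_antisense,
    }

    for entry in skeleton:
        gene: GeneModel = entry["gene"]
        contig = list(_random_background(rng, entry["contig_len"], config.background_gc))
        genes.append(gene)
        regions.extend(entry["regions"])
        occupied: list[tuple[int, int]] = []
        genic = entry["regions"][1]
        alu_serial = 0

        for region in entry["regions"]:
            for _ in range(entry["n_alus"][region.kind]):
                alu_strand = "+" if rng.random() < 0.5 else "-"
                orientation = "sense" if alu_strand == gene.strand else "antisense"

                planted_pos: int | None = None
                motif_word: str | None = None
                copy = config.alu_consensus
                protect = []
                if rng.random() < plant_prob[orientation]:
                    choices = config.plant_positions.get(orientation, ())
                    if choices:
                        planted_pos = int(choices[rng.integers(len(choices))])
                        motif_word = _resolve_motif(config.motif, rng)
                        copy = plant_motif(copy, motif_word, planted_pos)
                        if config.protect_planted:
                            protect = [(planted_pos - 1, planted_pos - 1 + MOTIF_WIDTH)]
                copy, new_starts = _mutate_tracked(
                    copy, config.alu_mutation_rate, config.indel_rate, rng, protect
                )
                if planted_pos is not None:
                    local_start = new_starts.get(planted_pos - 1, planted_pos - 1)
                else:
                    local_start = None
                if alu_strand == "-":
                    inserted = revcomp(copy)
                else:
                    inserted = copy

                # uniform non-overlapping placement within the region
                span = len(inserted)
                if region.length < span:
                    continue
                start = None
                for _attempt in range(50):
                    cand = int(rng.integers(region.start, region.end - span + 1))
                    if all(cand + span <= s or cand >= e for s, e in occupied):
                        start = cand
                        break
                if start is None:
                    continue
                occupied.append((start, start + span))
                contig[start : start + span] = inserted
                alu_serial += 1
                alu = AluElement(
                    alu_id=f"{gene.gene_id}_alu{alu_serial:03d}",
                    chrom=gene.chrom,
                    start=start,
                    end=start + span,
                    strand=alu_strand,
                    subfamily=config.subfamily,
                    host_gene=gene.gene_id,
                    orientation_class=orientation,
                    region_kind=region.kind,
                )
                alus.append(alu)

                if planted_pos is not None:
                    if alu_strand == "+":
                        g0 = start + local_start
                    else:  # motif reads on the Alu strand; mirror the offset
                        g0 = start + span - (local_start + MOTIF_WIDTH)
                    truth_rows.append(
                        {
                            "gene_id": gene.gene_id,
                            "alu_id": alu.alu_id,
                            "chrom": gene.chrom,
                            "start": g0,
                            "end": g0 + MOTIF_WIDTH,
                            "strand": alu_strand,
                            "orientation": orientation,
                            "region_kind": region.kind,
                            "consensus_position": planted_pos,
                            "motif_word": motif_word,
                        }
                    )
                    if (
                        gene.expression_class == "down"
                        and orientation == "antisense"
                        and region.kind == "genic"
                    ):
                        gap = int(round(config.antisense_signal_offset_kb * 1000))
                        if gene.strand == "+":
                            s1 = g0 - gap
                            s0 = s1 - config.signal_len
                        else:
                            s0 = g0 + MOTIF_WIDTH + gap
                            s1 = s0 + config.signal_len
                        if genic.start <= s0 and s1 <= genic.end:
                            signal_rows.append(
                                {
                                    "signal_id": f"sig_{gene.gene_id}_{len(signal_rows) + 1:04d}",
                                    "gene_id": gene.gene_id,
                                    "chrom": gene.chrom,
                                    "start": s0,
                                    "end": s1,
                                    "strand": "-" if gene.strand == "+" else "+",
                                    "detection_p": float(rng.uniform(0.0005, 0.02)),
                                }
                            )

        if gene.expression_class == "down" and rng.random() < config.noise_signal_prob:
            # an undetected decoy probe, exercising the detection filter
            if genic.length > config.signal_len:
                s0 = int(rng.integers(genic.start, genic.end - config.signal_len))
                signal_rows.append(
                    {
                        "signal_id": f"sig_{gene.gene_id}_{len(signal_rows) + 1:04d}",
                        "gene_id": gene.gene_id,
                        "chrom": gene.chrom,
                        "start": s0,
                        "end": s0 + config.signal_len,
                        "strand": "-" if gene.strand == "+" else "+",
                        "detection_p": float(rng.uniform(0.1, 0.9)),
                    }
                )
        genome[gene.chrom] = "".join(contig)

    signal_cols = ["signal_id", "gene_id", "chrom", "start", "end", "strand", "detection_p"]
    truth_cols = [
        "gene_id", "alu_id", "chrom", "start", "end", "strand",
        "orientation", "region_kind", "consensus_position", "motif_word",
    ]
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        regions=regions,
        alus=alus,
        signals=pd.DataFrame(signal_rows, columns=signal_cols),
        truth=pd.DataFrame(truth_rows, columns=truth_cols),
    )


def validate_dataset(ds: SyntheticDataset) -> None:
    """Check dataset invariants; raises AssertionError on violation.

    Every truth record's 13-mer must be retrievable from the genome at its
    recorded coordinates after strand adjustment, and every Alu must lie
    within its contig.
    """
    for _, row in ds.truth.iterrows():
        seq = ds.genome[row.chrom][row.start : row.end]
        if row.strand == "-":
            seq = revcomp(seq)
        assert seq == row.motif_word, (
            f"truth record {row.alu_id}: genome has {seq}, expected {row.motif_word}"
        )
    lengths = ds.contig_lengths
    for alu in ds.alus:
        assert 0 <= alu.start < alu.end <= lengths[alu.chrom], (
            f"{alu.alu_id} outside contig {alu.chrom}"
        )


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
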