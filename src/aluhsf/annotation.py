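"""Gene models, repeat annotations, analysis regions, and Alu orientation.

All internal coordinates are 0-based half-open; conversions to and from
1-based formats (RepeatMasker .out) happen only at I/O.  Gene records on
unplaced or haplotype contigs (``chr*_random``, ``chr*_hap*``) are dropped to
avoid ambiguous genomic locations.  Each gene contributes two analysis
regions: the 5-kb window upstream of the transcription start (on the gene's
own strand) and the genic body.  An Alu copy hosted by a gene is *sense* if
its strand matches the host transcript and *antisense* otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

AMBIGUOUS_CHROM = re.compile(r"(_random$|_hap)")

EXPRESSION_CLASSES = ("up", "down", "unchanged", "random")

DEFAULT_UPSTREAM_LEN = 5000


@dataclass
class GeneModel:
    """One pre-collapsed transcript interval with its expression class."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    expression_class: str = "unchanged"

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start must be < tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class AluElement:
    """One Alu repeat copy; orientation is relative to the host transcript."""

    alu_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    host_gene: str | None = None
    orientation_class: str | None = None
    region_kind: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.alu_id}: start must be < end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class RegionSpec:
    """An analysis window: the upstream 5 kb or the genic body of one gene."""

    gene_id: str
    kind: str  # 'upstream5kb' | 'genic'
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _read_class_table(class_table) -> Mapping[str, str]:
    if class_table is None:
        return {}
    if isinstance(class_table, Mapping):
        table = dict(class_table)
    else:
        table = {}
        with open(class_table) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(
                        f"{class_table}:{lineno}: expected gene_id<TAB>class"
                    )
                if parts[0] == "gene_id":  # header
                    continue
                table[parts[0]] = parts[1]
    for gid, cls in table.items():
        if cls not in EXPRESSION_CLASSES:
            raise ValueError(f"unknown expression class {cls!r} for gene {gid}")
    return table


def load_gene_models(path, class_table=None, fmt: str = "auto") -> list[GeneModel]:
    """Read gene models from BED12 or refFlat-style TSV.

    Ambiguous-location records (chromosome names matching ``*_random`` or
    ``*_hap``) are filtered out.  ``class_table`` maps gene_id to an
    expression class (``up``/``down``/``unchanged``/``random``); unlisted
    genes default to ``unchanged``.  Duplicate gene ids are an error.
    """
    classes = _read_class_table(class_table)
    if fmt == "auto":
        fmt = "bed12" if str(path).endswith((".bed", ".bed12")) else "refflat"
    if fmt not in ("bed12", "refflat"):
        raise ValueError(f"unknown gene-model format {fmt!r}")

    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if fmt == "bed12":
                    chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                    strand = parts[5] if len(parts) > 5 else "+"
                else:  # refFlat: geneName name chrom strand txStart txEnd ...
                    name, chrom, strand = parts[0], parts[2], parts[3]
                    start, end = int(parts[4]), int(parts[5])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable gene record") from exc
            if AMBIGUOUS_CHROM.search(chrom):
                continue
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            seen.add(name)
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    expression_class=classes.get(name, "unchanged"),
                )
            )
    return genes


def extract_regions(
    gene: GeneModel,
    contig_len: int,
    upstream_len: int = DEFAULT_UPSTREAM_LEN,
) -> tuple[RegionSpec, RegionSpec]:
    """Derive the (upstream, genic) analysis regions for one gene.

    The upstream window sits on the gene's own 5' side — before tx_start for
    a plus-strand gene, after tx_end for a minus-strand gene — and is
    truncated at the contig boundaries.
    """
    if gene.strand == "+":
        up = (max(0, gene.tx_start - upstream_len), gene.tx_start)
    else:
        up = (gene.tx_end, min(contig_len, gene.tx_end + upstream_len))
    upstream = RegionSpec(gene.gene_id, "upstream5kb", gene.chrom, up[0], up[1], gene.strand)
    genic = RegionSpec(
        gene.gene_id, "genic", gene.chrom, gene.tx_start, gene.tx_end, gene.strand
    )
    return upstream, genic


def load_alus(
    path,
    dialect: str,
    include_flam_fram: bool = False,
) -> list[AluElement]:
    """Read repeat annotations, keeping Alu-family records.

    ``repeatmasker_out`` rows are 1-based inclusive and use ``C`` for
    minus-strand matches; both are normalised here (0-based half-open,
    ``-``).  ``bed6`` rows carry the subfamily in the name column.  By
    default only subfamilies whose name starts with ``Alu`` are retained;
    ``include_flam_fram`` also keeps the FLAM/FRAM free monomers.
    """
    if dialect not in ("repeatmasker_out", "bed6"):
        raise ValueError(f"unknown repeat-annotation dialect {dialect!r}")

    prefixes = ("Alu", "FLAM", "FRAM") if include_flam_fram else ("Alu",)
    alus: list[AluElement] = []
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if dialect == "repeatmasker_out":
                parts = stripped.split()
                # the two header lines start with 'SW'/'score'
                if parts[0] in ("SW", "score", "bit"):
                    continue
                try:
                    chrom = parts[4]
                    start, end = int(parts[5]) - 1, int(parts[6])
                    strand = "-" if parts[8] == "C" else parts[8]
                    subfamily = parts[9]
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed .out record") from exc
            else:
                parts = stripped.split("\t")
                try:
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    subfamily = parts[3]
                    strand = parts[5] if len(parts) > 5 else "+"
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed BED6 record") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: malformed coordinates")
            if not subfamily.startswith(prefixes):
                continue
            n += 1
            alus.append(
                AluElement(
                    alu_id=f"alu{n:06d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    subfamily=subfamily,
                )
            )
    return alus


def assign_alu_orientation(alu: AluElement, gene: GeneModel) -> str:
    """Sense iff the Alu strand matches the host transcript strand."""
    if alu.strand not in ("+", "-"):
        raise ValueError(f"{alu.alu_id}: undefined strand {alu.strand!r}")
    if gene.strand not in ("+", "-"):
        raise ValueError(f"{gene.gene_id}: undefined strand {gene.strand!r}")
    return "sense" if alu.strand == gene.strand else "antisense"


def assign_alus_to_regions(
    alus: Iterable[AluElement],
    genes: Mapping[str, GeneModel],
    regions: Iterable[RegionSpec],
) -> list[AluElement]:
    """Attach each Alu to every region containing its midpoint.

    The midpoint rule gives a boundary-straddling Alu a single deterministic
    region, so per-region counts partition the hosted Alus.  An Alu whose
    midpoint falls in regions of two genes is duplicated, once per host, to
    keep counting per-transcript.  Returns new AluElement records with
    ``host_gene``, ``orientation_class`` and ``region_kind`` set.
    """
    by_chrom: dict[str, list[RegionSpec]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    hosted: list[AluElement] = []
    for alu in alus:
        mid = alu.midpoint
        for region in by_chrom.get(alu.chrom, ()):
            if region.start <= mid < region.end:
                gene = genes[region.gene_id]
                hosted.append(
                    AluElement(
                        alu_id=alu.alu_id,
                        chrom=alu.chrom,
                        start=alu.start,
                        end=alu.end,
                        strand=alu.strand,
                        subfamily=alu.subfamily,
                        host_gene=gene.gene_id,
                        orientation_class=assign_alu_orientation(alu, gene),
                        region_kind=region.kind,
                    )
                )
    return hosted
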