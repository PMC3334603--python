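"""Readers and writers for the standard text formats the pipeline touches.

All emitted BED is 0-based half-open; RepeatMasker ``.out`` is emitted
1-based inclusive with ``C`` for minus-strand copies, as the format
specifies.  FASTA goes through Biopython.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AluElement, GeneModel


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    """One-block BED12 per gene (pre-collapsed single-interval models)."""
    with open(path, "w") as fh:
        for g in genes:
            size = g.tx_end - g.tx_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                        g.tx_start, g.tx_end, 0, 1, f"{size},", "0,",
                    )
                )
                + "\n"
            )


def write_class_table(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression_class\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.expression_class}\n")


def write_bed6(alus: Iterable[AluElement], path) -> None:
    """BED6 with the subfamily in the name column."""
    with open(path, "w") as fh:
        for a in alus:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.subfamily}\t0\t{a.strand}\n"
            )


def write_repeatmasker_out(alus: Iterable[AluElement], path) -> None:
    """RepeatMasker-style ``.out``: 1-based inclusive, 'C' for minus strand."""
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, a in enumerate(alus, 1):
            strand = "C" if a.strand == "-" else "+"
            fh.write(
                f"  225  10.0  0.0  0.0  {a.chrom}  {a.start + 1}  {a.end}  (0)  "
                f"{strand}  {a.subfamily}  SINE/Alu  1  {a.end - a.start}  (0)  {i}\n"
            )


def write_signals(signals: pd.DataFrame, bed_path, tsv_path) -> None:
    """Antisense probe signals: BED6 plus a sidecar TSV with detection p."""
    with open(bed_path, "w") as fh:
        for _, r in signals.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.signal_id}\t0\t{r.strand}\n")
    signals[["signal_id", "gene_id", "detection_p"]].to_csv(
        tsv_path, sep="\t", index=False
    )


def read_signals(bed_path, tsv_path) -> pd.DataFrame:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "signal_id", "score", "strand"],
    )
    side = pd.read_csv(tsv_path, sep="\t")
    out = bed.merge(side, on="signal_id", how="left")
    if out["detection_p"].isna().any():
        missing = out.loc[out["detection_p"].isna(), "signal_id"].tolist()
        raise ValueError(f"signals missing detection p-values: {missing}")
    return out[["signal_id", "gene_id", "chrom", "start", "end", "strand", "detection_p"]]


def write_dataset(ds, outdir) -> dict[str, str]:
    """Write a synthetic dataset's files; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "genes_bed": os.path.join(outdir, "genes.bed"),
        "classes": os.path.join(outdir, "gene_classes.tsv"),
        "alus_bed": os.path.join(outdir, "alus.bed"),
        "alus_out": os.path.join(outdir, "alus.out"),
        "signals_bed": os.path.join(outdir, "antisense_signals.bed"),
        "signals_tsv": os.path.join(outdir, "antisense_signals.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "consensus": os.path.join(outdir, "alu_consensus.fa"),
    }
    write_fasta(ds.genome, paths["genome"])
    write_bed12(ds.genes, paths["genes_bed"])
    write_class_table(ds.genes, paths["classes"])
    write_bed6(ds.alus, paths["alus_bed"])
    write_repeatmasker_out(ds.alus, paths["alus_out"])
    write_signals(ds.signals, paths["signals_bed"], paths["signals_tsv"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    write_fasta({ds.config.subfamily: ds.config.alu_consensus}, paths["consensus"])
    return paths
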