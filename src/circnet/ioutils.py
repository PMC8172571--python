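"""Readers and writers for the pipeline's plain-text formats.

Counts and sample sheets are tab-separated; sequences are FASTA (written
and parsed with Biopython); annotation is standard 1-based-inclusive GTF;
caller tables are TSV with one reads_<sample> column per sample.
"""

from __future__ import annotations

import os

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .expression import ExpressionMatrix

__all__ = [
    "write_counts",
    "read_counts",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_fasta",
    "read_fasta",
    "write_gtf",
    "write_caller_table",
    "read_caller_table",
    "write_simulated_dataset",
]


def write_counts(matrix: ExpressionMatrix, path: str) -> None:
    frame = matrix.counts.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def read_counts(
    path: str, species: str, sample_sheet: pd.DataFrame, lengths: pd.Series | None = None
) -> ExpressionMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="feature_id")
    return ExpressionMatrix(species, counts, sample_sheet, lengths)


def write_sample_sheet(samples: pd.DataFrame, path: str) -> None:
    samples.reset_index().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("sample_id")


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_gtf(gtf: pd.DataFrame, path: str) -> None:
    gtf.to_csv(path, sep="\t", index=False, header=False)


def write_caller_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_caller_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_simulated_dataset(outdir: str, matrices, truth, sequences, tables) -> None:
    """Write one simulated dataset (counts, sheet, FASTA, caller TSVs, GTF)."""
    os.makedirs(outdir, exist_ok=True)
    samples = next(iter(matrices.values())).samples
    write_sample_sheet(samples, os.path.join(outdir, "samples.tsv"))
    for species, m in matrices.items():
        write_counts(m, os.path.join(outdir, f"counts_{species}.tsv"))
        if m.lengths is not None:
            m.lengths.rename("length").to_csv(
                os.path.join(outdir, f"lengths_{species}.tsv"), sep="\t"
            )
    for species, fname in (
        ("miRNA", "mirna.fa"),
        ("circRNA", "circ_exonic.fa"),
        ("mRNA", "utr3.fa"),
    ):
        write_fasta(sequences[species], os.path.join(outdir, fname))
    table_a, table_b, gtf = tables
    write_caller_table(table_a, os.path.join(outdir, "calls_callerA.tsv"))
    write_caller_table(table_b, os.path.join(outdir, "calls_callerB.tsv"))
    write_gtf(gtf, os.path.join(outdir, "annotation.gtf"))
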