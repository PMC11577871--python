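"""Readers and writers for the pipeline's file formats.

Tabular outputs are TSV with a header line; nested summaries are JSON.
The gene presence/absence reader understands both the plain dialect (first
column = gene family name, one column per genome, non-empty cell = present)
and full Roary ``gene_presence_absence.csv`` files, whose fixed metadata
columns are dropped.  Genome IDs are opaque, case-sensitive strings.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .delineation import ClusterPartition, ExclusionLedger
from .pangenome import PresenceAbsenceMatrix
from .similarity import SimilarityMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_roary_pam",
    "write_roary_pam",
    "read_labels_tsv",
    "write_labels_tsv",
    "write_ledger_tsv",
    "read_count_table",
]

# fixed metadata columns of Roary's gene_presence_absence.csv
_ROARY_META = [
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
]


def read_fasta(path) -> dict[str, str]:
    """Multi-record (multi-contig) FASTA into an ordered id -> sequence map."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for gid, seq in sequences.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_matrix_tsv(matrix: SimilarityMatrix, path) -> None:
    """Square matrix TSV: header row and first column are genome IDs."""
    with open(path, "w") as fh:
        fh.write("\t".join([""] + matrix.ids) + "\n")
        for gid, row in zip(matrix.ids, matrix.values):
            fh.write("\t".join([gid] + [f"{v:.4f}" for v in row]) + "\n")


def read_matrix_tsv(path, measure: str = "ANI") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError("matrix row and column IDs differ or are reordered")
    return SimilarityMatrix(ids, df.to_numpy(dtype=float), measure)


def read_roary_pam(path) -> PresenceAbsenceMatrix:
    """Gene presence/absence matrix from a Roary-dialect CSV.

    The first column holds gene family names; every remaining non-metadata
    column is a genome, and any non-empty cell (including semicolon-joined
    multi-copy locus tags) marks presence.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header:
            raise ValueError("empty presence/absence file")
        genome_cols = [
            (k, name) for k, name in enumerate(header[1:], start=1)
            if name not in _ROARY_META
        ]
        names = [name for _, name in genome_cols]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate genome column {dup!r}")
        genes: list[str] = []
        seen: set[str] = set()
        rows: list[list[bool]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            gene = row[0]
            if gene in seen:
                raise ValueError(f"duplicate gene name {gene!r} at line {lineno}")
            seen.add(gene)
            genes.append(gene)
            rows.append([bool(row[k].strip()) if k < len(row) else False
                         for k, _ in genome_cols])
    data = pd.DataFrame(rows, index=genes, columns=names, dtype=bool)
    return PresenceAbsenceMatrix(data)


def write_roary_pam(pam: PresenceAbsenceMatrix, path) -> None:
    """Write the plain Roary dialect: gene name column + one column per genome."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, quoting=csv.QUOTE_ALL)
        writer.writerow(["Gene"] + pam.genome_ids)
        arr = pam.data.to_numpy()
        for gene, row in zip(pam.gene_ids, arr):
            writer.writerow([gene] + [f"{gene}_{k}" if v else "" for k, v in
                                      enumerate(row)])


def read_labels_tsv(path) -> ClusterPartition:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    labels = {str(g): int(c) for g, c in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return ClusterPartition.from_raw_labels(list(labels), list(labels.values()))


def write_labels_tsv(partition: ClusterPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tcluster\n")
        for g, c in partition.labels.items():
            fh.write(f"{g}\t{c}\n")


def write_ledger_tsv(ledger: ExclusionLedger, path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tgenome\treason\n")
        for stage, gid, reason in ledger.to_rows():
            fh.write(f"{stage}\t{gid}\t{reason}\n")


def read_count_table(path) -> pd.DataFrame:
    """Strain x feature count TSV (BGC counts, COG profiles, ...)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    return df
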