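"""Readers and writers for the pipeline's plain-text interchange formats.

Sequence data move through FASTA/FASTQ (Biopython), supermatrices are
written as FASTA, relaxed PHYLIP and NEXUS with a RAxML-style partition
file, SNP matrices as TSV and a STRUCTURE-like two-row file, and
haplotype calls as a RADpainter tag-haplotype matrix (samples as
columns, one row per locus).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import _seq
from .assembly import ReadSet, ReferenceLoci
from .datasets import Dataset, SequenceDataset, SNPMatrix
from .matrix import LocusMatrix
from .simulate import SimulationConfig, SyntheticTruth, config_to_dict

__all__ = [
    "read_reads", "write_fastq", "write_fasta", "read_fasta",
    "write_phylip", "write_nexus", "write_partitions", "write_snp_tsv",
    "write_structure", "write_finerad", "write_truth", "write_config",
    "write_reference_fasta", "write_presence_matrix", "read_grouping",
]


def read_reads(path: str | Path, individual: str | None = None) -> ReadSet:
    """Load a FASTQ or FASTA read file into a ReadSet."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), fmt)]
    return ReadSet.from_sequences(individual or path.stem, seqs)


def write_fastq(readset: ReadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(readset.n_reads):
            seq = _seq.decode(readset.reads[i])
            fh.write(f"@{readset.individual}_r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# -- supermatrix ------------------------------------------------------------

def write_phylip(seqdata: SequenceDataset, path: str | Path) -> None:
    """Relaxed PHYLIP (full names, single space)."""
    with open(path, "w") as fh:
        fh.write(f" {len(seqdata.units)} {seqdata.total_length}\n")
        for unit in seqdata.units:
            fh.write(f"{unit} {seqdata.sequences[unit]}\n")


def write_nexus(seqdata: SequenceDataset, path: str | Path) -> None:
    units = seqdata.units
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(units)};\n  TAXLABELS\n")
        for u in units:
            fh.write(f"    {u}\n")
        fh.write("  ;\nEND;\n\nBEGIN CHARACTERS;\n")
        fh.write(f"  DIMENSIONS NCHAR={seqdata.total_length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
        for u in units:
            fh.write(f"    {u}  {seqdata.sequences[u]}\n")
        fh.write("  ;\nEND;\n")


def write_partitions(seqdata: SequenceDataset, path: str | Path) -> None:
    """RAxML-style partition file, one DNA partition per locus."""
    with open(path, "w") as fh:
        for locus, start, end in seqdata.partition:
            fh.write(f"DNA, {locus} = {start}-{end}\n")


# -- SNP formats ------------------------------------------------------------

def write_snp_tsv(snp: SNPMatrix, path: str | Path) -> None:
    cols = [f"{locus}:{col}" for locus, col in snp.site_map]
    frame = pd.DataFrame(snp.data, index=snp.units, columns=cols)
    frame.to_csv(path, sep="\t", index_label="unit", na_rep="NA")


def write_structure(dataset: Dataset, snp: SNPMatrix, path: str | Path) -> None:
    """STRUCTURE-like file: two rows per unit (up to two alleles per
    locus column), -9 for missing."""
    with open(path, "w") as fh:
        for unit in snp.units:
            for phase in range(2):
                row = []
                for locus, col in snp.site_map:
                    alleles = dataset.alleles(locus, unit)
                    if not alleles:
                        row.append("-9")
                        continue
                    base = alleles[min(phase, len(alleles) - 1)][col]
                    row.append("-9" if base in "N-" else str(int(_seq.encode(base)[0])))
                fh.write(unit + "\t" + "\t".join(row) + "\n")


def write_finerad(dataset: Dataset, path: str | Path) -> None:
    """RADpainter tag-haplotype matrix: sample names as the header row,
    then one row per locus with comma-separated haplotypes per sample."""
    units = list(dataset.units)
    with open(path, "w") as fh:
        fh.write("\t".join(units) + "\n")
        seen = set()
        for locus in dataset.loci:
            if locus in seen:
                continue
            seen.add(locus)
            row = [",".join(dataset.alleles(locus, u)) for u in units]
            fh.write("\t".join(row) + "\n")


# -- simulation artifacts ---------------------------------------------------

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    rows = [{"locus_id": t.locus_id, "label": t.label,
             "donor": t.donor or "", "recipient": t.recipient or "",
             "merged_from": ",".join(t.merged_from)} for t in truth.loci]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)


def write_reference_fasta(reference: ReferenceLoci, path: str | Path) -> None:
    write_fasta({l.locus_id: l.consensus for l in reference.loci}, path)


def write_presence_matrix(matrix: LocusMatrix, path: str | Path) -> None:
    """Loci x individuals table of allele counts (0 = missing)."""
    frame = pd.DataFrame(
        {ind: [len(matrix.alleles(l, ind)) for l in matrix.loci]
         for ind in matrix.individuals},
        index=matrix.loci)
    frame.to_csv(path, sep="\t", index_label="locus")


def read_grouping(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"individual", "population", "taxon"}
    if not required.issubset(df.columns):
        raise ValueError(f"grouping file needs columns {sorted(required)}")
    return df
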