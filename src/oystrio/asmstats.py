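"""Assembly, gene-set and read-set summary statistics.

Nx is the length of the sequence at which the cumulative
sorted-descending length first reaches x% of the total; Lx is its
1-based rank.  Gene length is the gene-feature span (introns included),
CDS length the sum of CDS segments; genes bin by CDS-segment count into
{1, 2-10, 11-20, >20}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import orthocomp


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_bp: int
    longest: int
    shortest: int
    mean_length: float
    n50: int
    l50: int
    n95: int
    l95: int


def _nx(sorted_desc: np.ndarray, total: int, x: float) -> tuple[int, int]:
    cum = np.cumsum(sorted_desc)
    idx = int(np.searchsorted(cum, x / 100.0 * total))
    return int(sorted_desc[idx]), idx + 1


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    if len(lengths) == 0:
        raise ValueError("no sequence lengths given")
    arr = np.asarray(lengths, dtype=np.int64)
    if (arr <= 0).any():
        raise ValueError("sequence lengths must be positive")
    arr = np.sort(arr)[::-1]
    total = int(arr.sum())
    n50, l50 = _nx(arr, total, 50)
    n95, l95 = _nx(arr, total, 95)
    return AssemblyStats(
        n_sequences=arr.size,
        total_bp=total,
        longest=int(arr[0]),
        shortest=int(arr[-1]),
        mean_length=total / arr.size,
        n50=n50,
        l50=l50,
        n95=n95,
        l95=l95,
    )


def mean_length(total_bp: float, n: int) -> float:
    """Mean feature length from a printed total and count."""
    if n <= 0:
        raise ValueError("count must be positive")
    return total_bp / n


def genome_fraction(feature_bp: float, genome_bp: float) -> float:
    """Fraction of the assembly covered by a feature class."""
    if genome_bp <= 0:
        raise ValueError("genome size must be positive")
    return feature_bp / genome_bp


CDS_BINS = ("1", "2-10", "11-20", ">20")


def cds_bin(n_cds: int) -> str:
    if n_cds <= 1:
        return "1"
    if n_cds <= 10:
        return "2-10"
    if n_cds <= 20:
        return "11-20"
    return ">20"


@dataclass(frozen=True)
class GeneSetStats:
    gene_count: int
    total_cds_bp: int
    mean_cds_length: float
    total_gene_bp: int
    mean_gene_length: float
    cds_bin_counts: dict[str, int]
    cds_bin_percent: dict[str, float]
    cds_genome_fraction: float | None
    gene_genome_fraction: float | None


def gene_set_stats(
    gff3: str | Mapping[str, orthocomp.GeneModel],
    assembly_size: int | None = None,
) -> GeneSetStats:
    """Gene-set summary from a GFF3 path/text or parsed gene models."""
    models = (
        gff3 if isinstance(gff3, Mapping) else orthocomp.read_gene_models(gff3)
    )
    usable = list(models.values())
    if len(usable) < len(models):
        warnings.warn("genes without CDS were excluded")
    if not usable:
        raise ValueError("no genes with CDS found")
    total_cds = sum(m.cds_length for m in usable)
    total_gene = sum(m.gene_end - m.gene_start for m in usable)
    bins = {b: 0 for b in CDS_BINS}
    for m in usable:
        bins[cds_bin(m.n_cds)] += 1
    n = len(usable)
    return GeneSetStats(
        gene_count=n,
        total_cds_bp=total_cds,
        mean_cds_length=total_cds / n,
        total_gene_bp=total_gene,
        mean_gene_length=total_gene / n,
        cds_bin_counts=bins,
        cds_bin_percent={b: 100.0 * c / n for b, c in bins.items()},
        cds_genome_fraction=(
            total_cds / assembly_size if assembly_size else None
        ),
        gene_genome_fraction=(
            total_gene / assembly_size if assembly_size else None
        ),
    )


@dataclass(frozen=True)
class ReadSetStats:
    n_reads: int
    total_bases: int
    mean_length: float
    q20_fraction: float
    q30_fraction: float
    coverage: float | None


def read_set_stats(
    fastq_path: str, genome_size: int | None = None
) -> ReadSetStats:
    """FASTQ summary (phred+33): counts, bases, Q20/Q30 base fractions."""
    n_reads = total = q20 = q30 = 0
    with open(fastq_path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or (
                len(seq) != len(qual)
            ):
                raise ValueError(f"malformed FASTQ record {n_reads + 1}")
            n_reads += 1
            total += len(seq)
            q = np.frombuffer(qual.encode(), np.uint8).astype(int) - 33
            q20 += int((q >= 20).sum())
            q30 += int((q >= 30).sum())
    if n_reads == 0:
        raise ValueError("empty FASTQ")
    return ReadSetStats(
        n_reads=n_reads,
        total_bases=total,
        mean_length=total / n_reads,
        q20_fraction=q20 / total,
        q30_fraction=q30 / total,
        coverage=(total / genome_size) if genome_size else None,
    )


def fasta_lengths(path: str) -> list[int]:
    from Bio import SeqIO

    return [len(rec.seq) for rec in SeqIO.parse(path, "fasta")]
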