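"""Synthetic trio, read, annotation and population generators.

Emulates the data structure of a hybrid-cross trio study: two parental
species genomes at a few percent sequence divergence (substitutions plus
small and >=50 bp indels), a hybrid offspring carrying one haplotype from
each parent, HiFi-like long reads and paired 150 bp short reads, gene
models with varying exon counts, and two populations sharing most SNPs
but fixed apart at a small fraction of sites.

Every generator is driven by a single integer seed and is byte-stable:
the same configuration always produces identical FASTA/FASTQ/GFF3/VCF
output.  Ground truth (read origins, planted variants, exact
ancestor-to-derived alignments) is retained so that downstream modules
can be tested as parameter-recovery problems.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
SMALL_INDEL_MAX = 49          # sizes 1..49 are "small"; >=50 is structural
LARGE_INDEL_MIN = 50
LARGE_INDEL_MAX = 10_000


class ConfigurationError(ValueError):
    """Raised when a simulation parameter is out of range."""


class CapacityError(ValueError):
    """Raised when requested features do not fit in the genome."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic trio.

    Rates are per-base probabilities relative to the ancestor sequence;
    ``substitution_rate`` is applied independently to each lineage, so a
    per-lineage rate of 0.01 yields ~2% substitution divergence between
    the two derived genomes.  Indel rates are per-base event densities;
    lengths are drawn from a geometric(small_indel_p) distribution
    truncated to [1, 49] for small events and a lognormal truncated to
    [50, 10000] for large ones.
    """

    seed: int = 42
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    substitution_rate: float = 0.01
    small_indel_rate: float = 1e-2
    large_indel_rate: float = 2e-4
    small_indel_p: float = 0.3
    large_indel_meanlog: float = math.log(150.0)
    large_indel_sdlog: float = 1.0
    within_species_heterozygosity: float = 0.025
    long_read_length_mean: int = 16_032
    long_read_sdlog: float = 0.2
    long_read_error: float = 1e-3
    short_read_length: int = 150
    short_fragment_length: int = 300
    coverage_long: float = 10.0
    coverage_short: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "small_indel_rate",
            "large_indel_rate",
            "within_species_heterozygosity",
            "long_read_error",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.genome_length < 10 * self.long_read_length_mean:
            raise ConfigurationError(
                "genome_length must be >= 10 * long_read_length_mean "
                f"({self.genome_length} < {10 * self.long_read_length_mean})"
            )


@dataclass(frozen=True)
class Variant:
    """One planted mutation, in ancestor coordinates."""

    lineage: str                    # "A" or "B"
    position: int                   # 0-based ancestor coordinate
    kind: str                       # substitution | small_indel | large_indel
    size: int                       # bp (1 for substitutions)
    is_insertion: bool = False


@dataclass
class TruthSet:
    """Simulator ground truth for parameter-recovery tests."""

    read_origin: dict[str, str] = field(default_factory=dict)
    planted_variants: list[Variant] = field(default_factory=list)
    # exact ancestor -> derived alignments, as (op, length) runs with
    # op in {"=", "X", "I", "D"}; keyed by lineage
    truth_cigars: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def variants(self, lineage: str) -> list[Variant]:
        return [v for v in self.planted_variants if v.lineage == lineage]


_BASE_LUT = np.frombuffer(BASES.encode(), np.uint8)


def random_genome(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform A/C/G/T ancestor sequence."""
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    return _BASE_LUT[codes].tobytes().decode()


def _classify_indel(size: int) -> str:
    return "small_indel" if size <= SMALL_INDEL_MAX else "large_indel"


def _draw_events(length: int, cfg: SimConfig, rng: np.random.Generator):
    """Draw substitution/indel events along one lineage, sorted by position."""
    events: list[tuple[int, str, int, bool]] = []  # (pos, kind, size, is_ins)
    sub_pos = np.flatnonzero(rng.random(length) < cfg.substitution_rate)
    for p in sub_pos:
        events.append((int(p), "substitution", 1, False))
    small_pos = np.flatnonzero(rng.random(length) < cfg.small_indel_rate)
    if small_pos.size:
        sizes = np.clip(
            rng.geometric(cfg.small_indel_p, size=small_pos.size), 1, SMALL_INDEL_MAX
        )
        ins = rng.random(small_pos.size) < 0.5
        for p, s, i in zip(small_pos, sizes, ins):
            events.append((int(p), "small_indel", int(s), bool(i)))
    large_pos = np.flatnonzero(rng.random(length) < cfg.large_indel_rate)
    if large_pos.size:
        sizes = np.clip(
            np.round(
                rng.lognormal(cfg.large_indel_meanlog, cfg.large_indel_sdlog,
                              size=large_pos.size)
            ).astype(int),
            LARGE_INDEL_MIN,
            LARGE_INDEL_MAX,
        )
        ins = rng.random(large_pos.size) < 0.5
        for p, s, i in zip(large_pos, sizes, ins):
            events.append((int(p), _classify_indel(int(s)), int(s), bool(i)))
    events.sort(key=lambda e: (e[0], e[1]))
    return events


def _intersects_protected(
    pos: int, size: int, is_ins: bool, starts: np.ndarray, ends: np.ndarray
) -> bool:
    if starts.size == 0:
        return False
    i = int(np.searchsorted(ends, pos, side="right"))
    if i >= starts.size:
        return False
    if is_ins:                       # insertions break only interior points
        return starts[i] < pos < ends[i]
    return pos + size > starts[i] and pos < ends[i]


def _mutate_lineage(
    ancestor: str,
    lineage: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    protected: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[str, list[Variant], list[tuple[str, int]]]:
    """Apply drawn events to the ancestor; return derived sequence,
    the surviving variant records and the exact alignment CIGAR.

    Indel events intersecting a protected interval are discarded
    (purifying selection against frame disruption); substitutions are
    unaffected.
    """
    n = len(ancestor)
    events = _draw_events(n, cfg, rng)
    if protected is not None:
        starts, ends = protected
        events = [
            (pos, kind, size, is_ins)
            for pos, kind, size, is_ins in events
            if kind == "substitution"
            or not _intersects_protected(pos, size, is_ins, starts, ends)
        ]
    out: list[str] = []
    cigar: list[tuple[str, int]] = []
    variants: list[Variant] = []

    def emit(op: str, ln: int) -> None:
        if ln <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    base_idx = {b: i for i, b in enumerate(BASES)}
    cursor = 0
    for pos, kind, size, is_ins in events:
        if pos < cursor:       # swallowed by a previous deletion / same site
            continue
        emit("=", pos - cursor)
        out.append(ancestor[cursor:pos])
        cursor = pos
        if kind == "substitution":
            old = ancestor[pos]
            new = BASES[(base_idx[old] + int(rng.integers(1, 4))) % 4]
            out.append(new)
            emit("X", 1)
            cursor += 1
            variants.append(Variant(lineage, pos, kind, 1))
        elif is_ins:
            ins_seq = random_genome(size, rng)
            out.append(ins_seq)
            emit("I", size)
            variants.append(Variant(lineage, pos, kind, size, True))
        else:
            size = min(size, n - pos)
            if size <= 0:
                continue
            emit("D", size)
            cursor += size
            variants.append(Variant(lineage, pos, _classify_indel(size), size))
    emit("=", n - cursor)
    out.append(ancestor[cursor:])
    return "".join(out), variants, cigar


def evolve_pair(
    ancestor: str,
    config: SimConfig,
    protected_intervals: Sequence[tuple[int, int]] | None = None,
) -> tuple[str, str, TruthSet]:
    """Derive two species genomes from an ancestor by independent mutation.

    Returns (genome_A, genome_B, truth); the truth set records every
    applied event (class assigned by the 50 bp size boundary) and the
    exact ancestor-to-derived alignment of each lineage.
    ``protected_intervals`` (0-based half-open, sorted, non-overlapping;
    e.g. CDS segments) reject intersecting indels, emulating purifying
    selection against frame disruption.
    """
    if not ancestor:
        raise ValueError("ancestor sequence is empty")
    if set(ancestor) - set(BASES):
        raise ValueError("ancestor must contain only A/C/G/T")
    protected = None
    if protected_intervals:
        ivals = sorted(protected_intervals)
        protected = (
            np.array([s for s, _ in ivals]),
            np.array([e for _, e in ivals]),
        )
    rng = np.random.default_rng(config.seed)
    rng_a, rng_b = rng.spawn(2)
    genome_a, var_a, cig_a = _mutate_lineage(ancestor, "A", config, rng_a, protected)
    genome_b, var_b, cig_b = _mutate_lineage(ancestor, "B", config, rng_b, protected)
    truth = TruthSet(
        planted_variants=var_a + var_b,
        truth_cigars={"A": cig_a, "B": cig_b},
    )
    return genome_a, genome_b, truth


def _heterozygous_copy(
    genome: str, rate: float, rng: np.random.Generator
) -> str:
    """Second haplotype differing at `rate` of sites (substitutions only)."""
    if rate == 0:
        return genome
    arr = np.frombuffer(genome.encode(), dtype=np.uint8).copy()
    idx = {ord(b): i for i, b in enumerate(BASES)}
    lut = np.zeros(256, np.uint8)
    for code, i in idx.items():
        lut[code] = i
    pos = np.flatnonzero(rng.random(arr.size) < rate)
    shift = rng.integers(1, 4, size=pos.size)
    new = (lut[arr[pos]] + shift) % 4
    arr[pos] = np.frombuffer(BASES.encode(), np.uint8)[new]
    return arr.tobytes().decode()


@dataclass
class Trio:
    parent_a: tuple[str, str]      # two haplotypes of the A-species parent
    parent_b: tuple[str, str]
    offspring: dict[str, str]      # {"A": haplotype, "B": haplotype}


def make_trio(
    genome_a: str, genome_b: str, config: SimConfig, truth: TruthSet | None = None
) -> tuple[Trio, TruthSet]:
    """Build a hybrid trio: diploid parents and a hybrid offspring that
    carries one haplotype sampled from each parent."""
    truth = truth if truth is not None else TruthSet()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    het = config.within_species_heterozygosity
    pa = (genome_a, _heterozygous_copy(genome_a, het, rng))
    pb = (genome_b, _heterozygous_copy(genome_b, het, rng))
    off_a = pa[int(rng.integers(0, 2))]
    off_b = pb[int(rng.integers(0, 2))]
    return Trio(pa, pb, {"A": off_a, "B": off_b}), truth


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSet:
    long_reads: list[tuple[str, str, str]] = field(default_factory=list)
    short_pairs: list[tuple[str, str, str, str, str]] = field(default_factory=list)
    # short pair record: (id, seq1, qual1, seq2, qual2)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    lut = np.zeros(256, np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    pos = np.flatnonzero(rng.random(arr.size) < rate)
    shift = rng.integers(1, 4, size=pos.size)
    new = (lut[arr[pos]] + shift) % 4
    arr[pos] = np.frombuffer(BASES.encode(), np.uint8)[new]
    return arr.tobytes().decode()


def _qual_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    return chr(q + 33)


def simulate_reads(
    haplotypes: Mapping[str, str],
    truth: TruthSet,
    config: SimConfig,
) -> tuple[ReadSet, TruthSet]:
    """Simulate offspring long (HiFi-like) and short paired reads.

    Long read lengths are lognormal with mean ``long_read_length_mean``;
    errors are substitutions only.  Read headers carry a running index
    and nothing about haplotype origin; origins go to the truth set.
    """
    if config.coverage_long < 0 or config.coverage_short < 0:
        raise ConfigurationError("coverage must be >= 0")
    if config.coverage_long == 0 and config.coverage_short == 0:
        raise ConfigurationError("at least one coverage must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    reads = ReadSet()
    qlong = _qual_char(config.long_read_error)
    mu = math.log(config.long_read_length_mean) - config.long_read_sdlog**2 / 2
    counter = 0
    for origin in sorted(haplotypes):
        hap = haplotypes[origin]
        L = len(hap)
        target = config.coverage_long * L
        total = 0
        while total < target:
            ln = int(round(rng.lognormal(mu, config.long_read_sdlog)))
            ln = max(100, min(ln, L))
            start = int(rng.integers(0, L - ln + 1))
            seq = _apply_errors(hap[start : start + ln], config.long_read_error, rng)
            rid = f"longread_{counter:08d}"
            counter += 1
            reads.long_reads.append((rid, seq, qlong * ln))
            truth.read_origin[rid] = origin
            total += ln
    counter = 0
    qshort = _qual_char(1e-3)
    for origin in sorted(haplotypes):
        hap = haplotypes[origin]
        L = len(hap)
        rl, fl = config.short_read_length, config.short_fragment_length
        n_pairs = int(config.coverage_short * L / (2 * rl))
        if n_pairs and L >= fl:
            starts = rng.integers(0, L - fl + 1, size=n_pairs)
            for start in starts:
                frag = hap[start : start + fl]
                r1 = _apply_errors(frag[:rl], 1e-3, rng)
                r2 = _apply_errors(
                    revcomp(frag[-rl:]), 1e-3, rng
                )
                rid = f"shortread_{counter:08d}"
                counter += 1
                reads.short_pairs.append((rid, r1, qshort * rl, r2, qshort * rl))
                truth.read_origin[rid] = origin
    return reads, truth


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fastq(records: Iterable[tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# population genotypes


@dataclass
class PopulationTruth:
    planted_specific: np.ndarray     # indices of near-fixed differentiated sites
    freq_a: np.ndarray
    freq_b: np.ndarray


def simulate_population_vcf(
    n_a: int,
    n_b: int,
    n_sites: int,
    fraction_differentiated: float,
    seed: int,
    vcf_path: str | None = None,
    popmap_path: str | None = None,
    chrom: str = "chr1",
    spacing: int = 100,
) -> tuple[str, pd.DataFrame, PopulationTruth]:
    """Two-population diploid genotypes as a VCF v4.2 string.

    Background sites share one allele frequency between populations;
    a ``fraction_differentiated`` of sites is planted with near-fixed
    differences (|p_A - p_B| > 0.95, emulating species-diagnostic SNPs).
    Genotypes are binomial(2, p) per individual.  Returns the VCF text,
    a sample-to-population map and the truth labels.
    """
    if not 0 <= fraction_differentiated <= 1:
        raise ConfigurationError("fraction_differentiated outside [0, 1]")
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    n_spec = int(round(fraction_differentiated * n_sites))
    planted = rng.choice(n_sites, size=n_spec, replace=False) if n_spec else np.array([], int)
    is_spec = np.zeros(n_sites, bool)
    is_spec[planted] = True

    base = rng.uniform(0.05, 0.95, size=n_sites)
    p_a = base.copy()
    p_b = base.copy()
    hi = rng.uniform(0.99, 1.0, size=n_sites)
    lo = rng.uniform(0.0, 0.01, size=n_sites)
    flip = rng.random(n_sites) < 0.5
    p_a[is_spec] = np.where(flip, hi, lo)[is_spec]
    p_b[is_spec] = np.where(flip, lo, hi)[is_spec]

    g_a = rng.binomial(2, p_a[:, None], size=(n_sites, n_a))
    g_b = rng.binomial(2, p_b[:, None], size=(n_sites, n_b))

    samples = [f"A{i:03d}" for i in range(n_a)] + [f"B{i:03d}" for i in range(n_b)]
    popmap = pd.DataFrame(
        {"sample": samples, "population": ["A"] * n_a + ["B"] * n_b}
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    ref_alt = np.array(list(BASES))[rng.integers(0, 4, size=(n_sites, 2))]
    # make REF != ALT
    same = ref_alt[:, 0] == ref_alt[:, 1]
    ref_alt[same, 1] = np.array(
        [BASES[(BASES.index(b) + 1) % 4] for b in ref_alt[same, 0]]
    )
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##contig=<ID={chrom},length={spacing * (n_sites + 1)}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(samples) + "\n")
    for i in range(n_sites):
        pos = spacing * (i + 1)
        gts = [gt_str[int(g)] for g in g_a[i]] + [gt_str[int(g)] for g in g_b[i]]
        buf.write(
            f"{chrom}\t{pos}\t.\t{ref_alt[i, 0]}\t{ref_alt[i, 1]}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
            + "\n"
        )
    vcf_text = buf.getvalue()
    if vcf_path:
        with open(vcf_path, "w") as fh:
            fh.write(vcf_text)
    if popmap_path:
        popmap.to_csv(popmap_path, sep="\t", index=False, header=False)
    truth = PopulationTruth(np.sort(planted), p_a, p_b)
    return vcf_text, popmap, truth


# ---------------------------------------------------------------------------
# gene annotations


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    start: int                     # 0-based
    cds_segments: list[tuple[int, int]]  # 0-based half-open, genomic order

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]


def simulate_gene_models(
    genome_length: int,
    n_genes: int,
    exon_count_distribution: Mapping[int, float],
    seed: int,
    chrom: str = "chr1",
    prefix: str = "gene",
    min_gap: int = 200,
    exon_len_range: tuple[int, int] = (120, 402),
    intron_len_range: tuple[int, int] = (60, 500),
) -> list[SimGene]:
    """Place non-overlapping gene models with exon counts drawn from the
    given distribution.  CDS lengths are forced to a multiple of three."""
    rng = np.random.default_rng(seed)
    counts = np.array(sorted(exon_count_distribution))
    probs = np.array([exon_count_distribution[c] for c in counts], float)
    probs = probs / probs.sum()
    genes: list[SimGene] = []
    cursor = min_gap
    for i in range(n_genes):
        n_exons = int(rng.choice(counts, p=probs))
        exon_lens = rng.integers(*exon_len_range, size=n_exons)
        exon_lens = (exon_lens // 3) * 3          # keep total CDS in frame
        exon_lens = np.maximum(exon_lens, 30)
        intron_lens = (
            rng.integers(*intron_len_range, size=n_exons - 1) if n_exons > 1 else []
        )
        start = cursor + int(rng.integers(0, min_gap))
        segs = []
        pos = start
        for j in range(n_exons):
            segs.append((pos, pos + int(exon_lens[j])))
            pos = segs[-1][1]
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        if pos + min_gap > genome_length:
            raise CapacityError(
                f"genome of {genome_length} bp cannot hold {n_genes} genes "
                f"(stopped after {i})"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(SimGene(f"{prefix}{i + 1:05d}", chrom, strand, start, segs))
        cursor = pos + min_gap
    return genes


_STOP_FIX = {"TAA": "TTA", "TAG": "TTG", "TGA": "TGG"}  # Leu/Leu/Trp
_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def sanitize_orfs(ancestor: str, genes: Sequence[SimGene]) -> str:
    """Rewrite the ancestor so each gene's spliced CDS is a stop-free ORF.

    In-frame stop codons are converted by a single-base edit (TAA->TTA,
    TAG->TTG, TGA->TGG), applied in genomic coordinates with
    strand-aware complementation.  Returns the edited sequence.
    """
    arr = list(ancestor)
    for g in genes:
        coords: list[int] = []
        if g.strand == "+":
            for s, e in g.cds_segments:
                coords.extend(range(s, e))
        else:
            for s, e in reversed(g.cds_segments):
                coords.extend(range(e - 1, s - 1, -1))
        coding = [
            arr[p] if g.strand == "+" else _COMP_BASE[arr[p]] for p in coords
        ]
        for i in range(0, len(coding) - len(coding) % 3, 3):
            codon = "".join(coding[i : i + 3])
            if codon in _STOP_FIX:
                fixed = _STOP_FIX[codon]
                for j in range(3):
                    coding[i + j] = fixed[j]
                    p = coords[i + j]
                    arr[p] = fixed[j] if g.strand == "+" else _COMP_BASE[fixed[j]]
    return "".join(arr)


def genes_to_gff3(genes: Sequence[SimGene], source: str = "oystrio") -> str:
    """Serialize gene models as GFF3 (gene/mRNA/CDS; 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in genes:
        gstart, gend = g.start + 1, g.end
        lines.append(
            f"{g.chrom}\t{source}\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chrom}\t{source}\tmRNA\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
            f"ID={mrna};Parent={g.gene_id}"
        )
        segs = g.cds_segments if g.strand == "+" else g.cds_segments[::-1]
        phase = 0
        for s, e in segs:
            lines.append(
                f"{g.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                f"ID={mrna}.cds;Parent={mrna}"
            )
            phase = (3 - ((e - s) - phase) % 3) % 3
    return "\n".join(lines) + "\n"


def simulate_annotations(
    genome: str,
    n_genes: int,
    exon_count_distribution: Mapping[int, float],
    seed: int,
    chrom: str = "chr1",
    prefix: str = "gene",
) -> tuple[str, list[SimGene]]:
    """GFF3 annotation for one genome; returns (gff3 text, gene models)."""
    genes = simulate_gene_models(
        len(genome), n_genes, exon_count_distribution, seed, chrom, prefix
    )
    return genes_to_gff3(genes), genes


# ---- projection of ancestor annotations through truth alignments ----------


def _cigar_maps(cigar: Sequence[tuple[str, int]]):
    """Prefix tables mapping ancestor coordinates to derived coordinates."""
    anc_starts, der_starts, anc_lens = [], [], []
    a = d = 0
    for op, ln in cigar:
        if op in "=XD":
            anc_starts.append(a)
            der_starts.append(d)
            anc_lens.append(ln if op != "D" else 0)
            a += ln
            if op != "D":
                d += ln
        elif op == "I":
            d += ln
    return np.array(anc_starts), np.array(der_starts), np.array(anc_lens)


def project_position(pos: int, maps) -> int:
    """Map an ancestor coordinate to the derived genome (left-nearest base)."""
    anc_starts, der_starts, anc_lens = maps
    i = int(np.searchsorted(anc_starts, pos, side="right")) - 1
    off = min(pos - anc_starts[i], anc_lens[i])
    return int(der_starts[i] + off)


def _cds_hit_by_indel(gene: SimGene, variants: Sequence[Variant]) -> bool:
    """Does any planted indel intersect a CDS segment of the gene?"""
    for v in variants:
        if v.kind == "substitution":
            continue
        if v.is_insertion:
            lo, hi = v.position, v.position
        else:
            lo, hi = v.position, v.position + v.size
        for s, e in gene.cds_segments:
            if v.is_insertion:
                if s < v.position < e:
                    return True
            elif lo < e and hi > s:
                return True
    return False


def simulate_ortholog_annotations(
    ancestor_length: int,
    truth: TruthSet,
    n_genes: int,
    exon_count_distribution: Mapping[int, float],
    seed: int,
    chrom_a: str = "chrA1",
    chrom_b: str = "chrB1",
    genes: Sequence[SimGene] | None = None,
    require_intact_cds: bool = True,
) -> tuple[str, str, pd.DataFrame]:
    """Homologous annotations for the two derived genomes.

    Genes are placed on the ancestor (or passed in pre-placed) and their
    exon boundaries projected through each lineage's truth alignment.
    With ``require_intact_cds`` (default), genes whose CDS intersects a
    planted indel in either lineage are dropped from both annotations —
    a coding-frame conservation filter, so surviving ortholog pairs have
    in-frame comparable CDSs while introns and flanks keep their indels.
    Returns (gff3_A, gff3_B, orthogroup table).
    """
    anc_genes = (
        list(genes)
        if genes is not None
        else simulate_gene_models(
            ancestor_length, n_genes, exon_count_distribution, seed, "anc", "g"
        )
    )
    maps = {lin: _cigar_maps(truth.truth_cigars[lin]) for lin in ("A", "B")}
    indels = {
        lin: [v for v in truth.variants(lin) if v.kind != "substitution"]
        for lin in ("A", "B")
    }
    genes_a, genes_b, rows = [], [], []
    kept = 0
    for g in anc_genes:
        if require_intact_cds and any(
            _cds_hit_by_indel(g, indels[lin]) for lin in ("A", "B")
        ):
            continue
        projected = {}
        ok = True
        for lin in ("A", "B"):
            segs = []
            for s, e in g.cds_segments:
                ps, pe = project_position(s, maps[lin]), project_position(e, maps[lin])
                if pe - ps < 3:
                    ok = False
                segs.append((ps, pe))
            projected[lin] = segs
        if not ok:
            continue
        kept += 1
        ga = SimGene(f"geneA{kept:05d}", chrom_a, g.strand, projected["A"][0][0],
                     projected["A"])
        gb = SimGene(f"geneB{kept:05d}", chrom_b, g.strand, projected["B"][0][0],
                     projected["B"])
        genes_a.append(ga)
        genes_b.append(gb)
        og = f"OG{kept:05d}"
        rows.append((og, "speciesA", ga.gene_id))
        rows.append((og, "speciesB", gb.gene_id))
    table = pd.DataFrame(rows, columns=["group_id", "species", "gene_id"])
    return genes_to_gff3(genes_a), genes_to_gff3(genes_b), table
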