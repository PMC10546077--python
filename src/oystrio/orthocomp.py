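"""Ortholog gene-pair comparison between two genomes.

Given GFF3 annotations, genome sequences and an orthogroup table, this
module extracts all cross-species gene pairs, compares gene structure
(equal CDS-segment counts), measures per-region BLAST identities
(spliced CDS, peptide, introns, ten 1-kb upstream and downstream
windows), censuses alignment indels per region, tests the
identity-vs-distance trend of the flank windows (Mann–Kendall) and the
same-structure/different-structure identity contrast (Welch t), and
estimates Ka/Ks by the NG86 counting method.

Region identities come from global pairwise alignment with affine gap
costs (match +2, mismatch -3, gap open 5, extend 2, a gap of length g
costing open + g*extend); identity is matches over all alignment
columns, the same gap-uncompressed definition used for whole-genome
blocks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

from .ng86 import KaKsResult, kaks_ng86
from .synthio import revcomp

FLANK_WINDOW = 1000
N_FLANK_WINDOWS = 10
DEFAULT_SCORES = {"match": 2, "mismatch": -3, "gap_open": 5, "gap_extend": 2}
CONSERVED_IDENTITY = 0.90


@dataclass
class GeneModel:
    """Representative (longest-CDS) transcript of one gene."""

    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]      # 0-based half-open, genomic order
    gene_start: int                           # 0-based
    gene_end: int

    @property
    def n_cds(self) -> int:
        return len(self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    def spliced_cds(self, genome: Mapping[str, str]) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.cds_segments)
        return revcomp(seq) if self.strand == "-" else seq

    def peptide(self, genome: Mapping[str, str]) -> str:
        cds = self.spliced_cds(genome)
        cds = cds[: len(cds) - len(cds) % 3]
        pep = str(Seq(cds).translate())
        return pep.rstrip("*")

    def introns(self, genome: Mapping[str, str]) -> list[str]:
        segs = self.cds_segments
        out = [genome[self.chrom][segs[i][1]: segs[i + 1][0]]
               for i in range(len(segs) - 1)]
        if self.strand == "-":
            out = [revcomp(s) for s in reversed(out)]
        return out

    def flank_window(
        self, genome: Mapping[str, str], side: str, index: int
    ) -> tuple[str, bool]:
        """1-kb flank window (index 1..10, nearest first), strand-aware.

        Returns (sequence, truncated_flag); windows are clipped at
        chromosome ends and flagged when clipped.
        """
        if side not in ("up", "dn"):
            raise ValueError("side must be 'up' or 'dn'")
        chrom_len = len(genome[self.chrom])
        left_of_gene = (side == "up") == (self.strand == "+")
        if left_of_gene:
            end = self.gene_start - (index - 1) * FLANK_WINDOW
            start = end - FLANK_WINDOW
        else:
            start = self.gene_end + (index - 1) * FLANK_WINDOW
            end = start + FLANK_WINDOW
        cstart, cend = max(0, start), min(chrom_len, end)
        truncated = (cstart, cend) != (start, end)
        seq = genome[self.chrom][cstart:cend] if cend > cstart else ""
        if self.strand == "-":
            seq = revcomp(seq)
        return seq, truncated


def read_gene_models(gff3: str) -> dict[str, GeneModel]:
    """Parse GFF3 into representative gene models (longest CDS per gene)."""
    db = gffutils.create_db(
        gff3,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        from_string=gff3.lstrip().startswith("##gff"),
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best: GeneModel | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = sorted(
                (c.start - 1, c.end)
                for c in db.children(mrna, featuretype="CDS")
            )
            if not segs:
                continue
            model = GeneModel(
                gene.id, gene.seqid, gene.strand, segs,
                gene.start - 1, gene.end,
            )
            if best is None or model.cds_length > best.cds_length:
                best = model
        if best is None:
            segs = sorted(
                (c.start - 1, c.end)
                for c in db.children(gene, featuretype="CDS")
            )
            if segs:
                best = GeneModel(gene.id, gene.seqid, gene.strand, segs,
                                 gene.start - 1, gene.end)
        if best is not None:
            models[gene.id] = best
    return models


@dataclass
class OrthologPair:
    gene_a: GeneModel
    gene_b: GeneModel
    group_id: str
    subtype: str                            # one-to-one | one-to-many | ...
    identities: dict[str, float | None] = field(default_factory=dict)
    indel_runs: dict[str, list[int]] = field(default_factory=dict)
    kaks: KaKsResult | None = None

    @property
    def same_structure(self) -> bool:
        return self.gene_a.n_cds == self.gene_b.n_cds

    @property
    def highly_conserved(self) -> bool:
        cds = self.identities.get("cds")
        pep = self.identities.get("pep")
        return (
            self.same_structure
            and cds is not None and cds > CONSERVED_IDENTITY
            and pep is not None and pep > CONSERVED_IDENTITY
        )


def _subtype(n_a: int, n_b: int) -> str:
    left = "one" if n_a == 1 else "many"
    right = "one" if n_b == 1 else "many"
    return f"{left}-to-{right}"


def extract_pairs(
    orthogroups: pd.DataFrame,
    models_a: Mapping[str, GeneModel],
    models_b: Mapping[str, GeneModel],
    species_a: str = "speciesA",
    species_b: str = "speciesB",
) -> list[OrthologPair]:
    """All A-by-B gene pairs within each orthogroup.

    The table needs columns group_id, species, gene_id; every gene id
    must resolve in the corresponding annotation.
    """
    missing = []
    for _, row in orthogroups.iterrows():
        pool = models_a if row["species"] == species_a else models_b
        if row["gene_id"] not in pool:
            missing.append(row["gene_id"])
    if missing:
        raise KeyError(f"gene ids not found in annotations: {missing[:10]}")
    pairs: list[OrthologPair] = []
    for gid, grp in orthogroups.groupby("group_id", sort=True):
        ids_a = grp.loc[grp["species"] == species_a, "gene_id"].tolist()
        ids_b = grp.loc[grp["species"] == species_b, "gene_id"].tolist()
        if not ids_a or not ids_b:
            continue
        sub = _subtype(len(ids_a), len(ids_b))
        for ga in ids_a:
            for gb in ids_b:
                pairs.append(OrthologPair(models_a[ga], models_b[gb], gid, sub))
    return pairs


def make_aligner(scores: Mapping[str, float] = DEFAULT_SCORES) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores["match"]
    aligner.mismatch_score = scores["mismatch"]
    aligner.open_gap_score = -(scores["gap_open"] + scores["gap_extend"])
    aligner.extend_gap_score = -scores["gap_extend"]
    return aligner


def alignment_stats(alignment) -> tuple[int, int, list[int]]:
    """(matches, columns, gap run lengths) of one pairwise alignment."""
    a, b = alignment[0], alignment[1]
    matches = 0
    gap_runs: list[int] = []
    run = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            run += 1
            continue
        if run:
            gap_runs.append(run)
            run = 0
        if ca == cb:
            matches += 1
    if run:
        gap_runs.append(run)
    return matches, len(a), gap_runs


def sequence_identity(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> tuple[float | None, list[int]]:
    """Gap-uncompressed identity of the optimal global alignment, plus
    gap run lengths.  Empty input on either side reports None."""
    if not seq_a or not seq_b:
        return None, []
    aligner = aligner or make_aligner()
    alignment = aligner.align(seq_a, seq_b)[0]
    matches, columns, gap_runs = alignment_stats(alignment)
    return matches / columns, gap_runs


REGIONS = (
    ["cds", "pep", "int"]
    + [f"up{i}k" for i in range(1, N_FLANK_WINDOWS + 1)]
    + [f"dn{i}k" for i in range(1, N_FLANK_WINDOWS + 1)]
)


def region_sequences(
    gene: GeneModel, genome: Mapping[str, str], region: str
) -> tuple[str, bool]:
    """(sequence, truncated) for one named region of a gene."""
    if region == "cds":
        return gene.spliced_cds(genome), False
    if region == "pep":
        return gene.peptide(genome), False
    if region == "int":
        return "".join(gene.introns(genome)), False
    side, idx = region[:2], int(region[2:-1])
    return gene.flank_window(genome, side, idx)


def region_identity(
    pair: OrthologPair,
    genome_a: Mapping[str, str],
    genome_b: Mapping[str, str],
    region: str,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[float | None, list[int]]:
    sa, _ = region_sequences(pair.gene_a, genome_a, region)
    sb, _ = region_sequences(pair.gene_b, genome_b, region)
    return sequence_identity(sa, sb, aligner)


def compare_pair(
    pair: OrthologPair,
    genome_a: Mapping[str, str],
    genome_b: Mapping[str, str],
    regions: Sequence[str] = REGIONS,
    aligner: Align.PairwiseAligner | None = None,
    with_kaks: bool = True,
) -> OrthologPair:
    """Fill identities, indel census material and Ka/Ks for one pair."""
    aligner = aligner or make_aligner()
    for region in regions:
        ide, gaps = region_identity(pair, genome_a, genome_b, region, aligner)
        pair.identities[region] = ide
        pair.indel_runs[region] = gaps
    if with_kaks:
        cds_a = pair.gene_a.spliced_cds(genome_a)
        cds_b = pair.gene_b.spliced_cds(genome_b)
        pair.kaks = kaks_from_alignment(cds_a, cds_b, aligner)
    return pair


def kaks_from_alignment(
    cds_a: str, cds_b: str, aligner: Align.PairwiseAligner | None = None
) -> KaKsResult | None:
    """Align two CDSs, drop gapped codon columns, run NG86.

    Unequal-length CDS pairs are reconciled by global alignment; every
    codon with a gap in either sequence is excluded."""
    aligner = aligner or make_aligner()
    if not cds_a or not cds_b:
        return None
    if len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0 and cds_a == cds_b:
        return kaks_ng86(cds_a, cds_b)
    alignment = aligner.align(cds_a, cds_b)[0]
    a, b = str(alignment[0]), str(alignment[1])
    kept_a: list[str] = []
    kept_b: list[str] = []
    # walk codons of sequence A along the alignment; keep gap-free codons
    codon_a: list[str] = []
    codon_b: list[str] = []
    for ca, cb in zip(a, b):
        if ca == "-":
            continue
        codon_a.append(ca)
        codon_b.append(cb)
        if len(codon_a) == 3:
            ca, cb = "".join(codon_a), "".join(codon_b)
            # keep gap-free, stop-free codon columns only
            if "-" not in cb and not _is_stop(ca) and not _is_stop(cb):
                kept_a.append(ca)
                kept_b.append(cb)
            codon_a, codon_b = [], []
    if len(kept_a) < 1:
        return None
    try:
        return kaks_ng86("".join(kept_a), "".join(kept_b))
    except ValueError:
        return None


def _is_stop(codon: str) -> bool:
    from .ng86 import STOP, _AMBIGUOUS, translate_codon

    if set(codon.upper()) & _AMBIGUOUS:
        return False
    try:
        return translate_codon(codon) == STOP
    except KeyError:
        return False


def indel_census(
    pairs: Iterable[OrthologPair],
    thresholds: Sequence[int] = (10, 50),
    regions: Sequence[str] = ("cds", "int", "up2k", "dn2k"),
) -> pd.DataFrame:
    """Pairs harbouring a gap run strictly greater than each threshold.

    Returns a region x threshold table of pair counts (a pair counts
    once per cell regardless of how many qualifying runs it has).
    """
    counts = {(r, t): 0 for r in regions for t in thresholds}
    for pair in pairs:
        for region in regions:
            runs = pair.indel_runs.get(region, [])
            for t in thresholds:
                if any(g > t for g in runs):
                    counts[(region, t)] += 1
    return pd.DataFrame(
        {f">{t}bp": [counts[(r, t)] for r in regions] for t in thresholds},
        index=list(regions),
    )


def mann_kendall(values: Sequence[float]) -> tuple[int, float, float]:
    """Mann–Kendall trend test: (S, tau, two-sided p).

    Normal approximation with the standard tie correction and
    continuity correction.
    """
    x = np.asarray(values, float)
    n = x.size
    if n < 3:
        raise ValueError("Mann–Kendall needs at least 3 values")
    s = 0
    for i in range(n - 1):
        s += int(np.sign(x[i + 1 :] - x[i]).sum())
    denom = n * (n - 1) / 2
    tau = s / denom
    _, tie_counts = np.unique(x, return_counts=True)
    var = (
        n * (n - 1) * (2 * n + 5)
        - sum(t * (t - 1) * (2 * t + 5) for t in tie_counts)
    ) / 18.0
    if var == 0:
        return s, tau, 1.0
    if s > 0:
        z = (s - 1) / math.sqrt(var)
    elif s < 0:
        z = (s + 1) / math.sqrt(var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, tau, p


def flank_trend(identities: Sequence[float]) -> tuple[int, float, float]:
    """Trend of mean flank identities ordered by distance from the CDS."""
    return mann_kendall(identities)


def pairs_table(pairs: Iterable[OrthologPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        row = {
            "group_id": p.group_id,
            "gene_a": p.gene_a.gene_id,
            "gene_b": p.gene_b.gene_id,
            "subtype": p.subtype,
            "same_structure": p.same_structure,
            "highly_conserved": p.highly_conserved,
        }
        row.update({k: v for k, v in p.identities.items()})
        if p.kaks is not None:
            row.update(
                {"ka": p.kaks.ka, "ks": p.kaks.ks, "kaks": p.kaks.ratio,
                 "kaks_p": p.kaks.p_value}
            )
        rows.append(row)
    return pd.DataFrame(rows)


def structure_and_identity_contrast(
    pairs: Iterable[OrthologPair],
    regions: Sequence[str] = ("cds", "pep", "int", "up10k", "dn10k"),
) -> pd.DataFrame:
    """Mean identity per region by gene-structure stratum, with Welch t.

    With a single stratum the means are reported and the test skipped.
    """
    table = pairs_table(pairs)
    rows = []
    for region in regions:
        if region not in table:
            continue
        same = table.loc[table["same_structure"], region].dropna()
        diff = table.loc[~table["same_structure"], region].dropna()
        row = {
            "region": region,
            "mean_same_structure": same.mean() if len(same) else np.nan,
            "mean_diff_structure": diff.mean() if len(diff) else np.nan,
            "n_same": len(same),
            "n_diff": len(diff),
        }
        if len(same) >= 2 and len(diff) >= 2:
            t, p = stats.ttest_ind(same, diff, equal_var=False)
            row["welch_t"] = float(t)
            row["welch_p"] = float(p)
        else:
            warnings.warn(f"{region}: a stratum has <2 pairs; Welch test skipped")
            row["welch_t"] = np.nan
            row["welch_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
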