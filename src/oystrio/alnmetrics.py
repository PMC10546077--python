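"""Whole-genome alignment identity metrics and divergence decomposition.

Consumes PAF records with extended CIGARs (``cg:Z`` tag using =/X/I/D
operations, as produced by an aligner run with ``-c --eqx``) and
computes, per aligned block, both the gap-uncompressed BLAST identity
(matches over all alignment columns including gaps) and the
gap-compressed identity (matches over matches + mismatches + gap
openings, each maximal run of gap characters counting once).

Genome-wide divergence is decomposed into three components on the
column denominator: nucleotide substitution (mismatch columns), small
indels (<50 bp gap runs) and large indels (>=50 bp gap runs, the usual
structural-variant size class).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

CIGAR_RE = re.compile(r"(\d+)([A-Z=])")
SV_SIZE_THRESHOLD = 50


class PafError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned segment with parsed =/X/I/D runs (0-based half-open)."""

    query_chrom: str
    query_start: int
    query_end: int
    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    cigar: tuple[tuple[str, int], ...]

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    def validate(self) -> None:
        if any(ln <= 0 for _, ln in self.cigar):
            raise PafError("zero-length CIGAR run")
        tspan = sum(ln for op, ln in self.cigar if op in "=XD")
        qspan = sum(ln for op, ln in self.cigar if op in "=XI")
        if tspan != self.target_span or qspan != self.query_span:
            raise PafError(
                f"CIGAR spans (query {qspan}, target {tspan}) disagree with "
                f"coordinates (query {self.query_span}, target {self.target_span})"
            )


def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    runs = []
    pos = 0
    for m in CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise PafError(f"malformed CIGAR near {text[pos:pos + 10]!r}")
        pos = m.end()
        ln, op = int(m.group(1)), m.group(2)
        if op == "M":
            raise PafError(
                "CIGAR uses M; an extended (=/X) CIGAR is required"
            )
        if op not in "=XID":
            raise PafError(f"unsupported CIGAR op {op!r}")
        runs.append((op, ln))
    if pos != len(text):
        raise PafError(f"malformed CIGAR near {text[pos:pos + 10]!r}")
    return tuple(runs)


def read_paf(path: str) -> list[AlignmentBlock]:
    """Parse a PAF file with cg:Z extended CIGAR tags."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise PafError(f"line {lineno}: fewer than 12 PAF columns")
            cg = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
                    break
            if cg is None:
                raise PafError(f"line {lineno}: missing cg:Z CIGAR tag")
            block = AlignmentBlock(
                query_chrom=fields[0],
                query_start=int(fields[2]),
                query_end=int(fields[3]),
                strand=fields[4],
                target_chrom=fields[5],
                target_start=int(fields[7]),
                target_end=int(fields[8]),
                cigar=parse_cigar(cg),
            )
            try:
                block.validate()
            except PafError as exc:
                raise PafError(f"line {lineno}: {exc}") from None
            blocks.append(block)
    return blocks


def filter_blocks(
    blocks: Iterable[AlignmentBlock], min_len: int = 1000
) -> list[AlignmentBlock]:
    """Retain blocks whose target span is strictly greater than min_len."""
    return [b for b in blocks if b.target_span > min_len]


@dataclass(frozen=True)
class IdentityMetrics:
    columns: int
    matches: int
    mismatches: int
    indel_bases: int
    gap_opens: int

    @property
    def ide1(self) -> float:
        """BLAST (gap-uncompressed) identity: matches / all columns."""
        return self.matches / self.columns if self.columns else 0.0

    @property
    def ide2(self) -> float:
        """Gap-compressed identity: each maximal gap run counts once."""
        denom = self.matches + self.mismatches + self.gap_opens
        return self.matches / denom if denom else 0.0


def block_identity(block: AlignmentBlock) -> IdentityMetrics:
    m = mm = ind = opens = 0
    for op, ln in block.cigar:
        if op == "=":
            m += ln
        elif op == "X":
            mm += ln
        else:
            ind += ln
            opens += 1          # each maximal I or D run is one gap opening
    return IdentityMetrics(m + mm + ind, m, mm, ind, opens)


@dataclass(frozen=True)
class DivergenceDecomposition:
    total_alignment_bp: float
    match_bp: float
    mismatch_bp: float
    indel_bp: float
    large_indel_bp: float
    size_threshold: int = SV_SIZE_THRESHOLD

    @property
    def rate_mismatch(self) -> float:
        return self.mismatch_bp / self.total_alignment_bp

    @property
    def rate_small_indel(self) -> float:
        return (self.indel_bp - self.large_indel_bp) / self.total_alignment_bp

    @property
    def rate_large_indel(self) -> float:
        return self.large_indel_bp / self.total_alignment_bp

    @property
    def rate_total_uncompressed(self) -> float:
        return (self.mismatch_bp + self.indel_bp) / self.total_alignment_bp

    @property
    def large_indel_fraction_of_indel(self) -> float:
        return self.large_indel_bp / self.indel_bp if self.indel_bp else 0.0


def decompose_divergence(
    total_bp: float,
    match_bp: float,
    mismatch_bp: float,
    indel_bp: float,
    large_indel_bp: float,
    size_threshold: int = SV_SIZE_THRESHOLD,
    rtol: float = 1e-3,
) -> DivergenceDecomposition:
    """Divergence decomposition from printed or computed aggregates.

    The aggregates must satisfy match + mismatch + indel = total up to
    ``rtol`` (published totals are rounded); the residual is reported on
    failure.
    """
    residual = total_bp - (match_bp + mismatch_bp + indel_bp)
    if abs(residual) > rtol * total_bp:
        raise ValueError(
            "inconsistent aggregates: match + mismatch + indel differs from "
            f"total by {residual:g} bp ({residual / total_bp:.3%})"
        )
    if large_indel_bp > indel_bp:
        raise ValueError("large_indel_bp exceeds indel_bp")
    return DivergenceDecomposition(
        total_bp, match_bp, mismatch_bp, indel_bp, large_indel_bp, size_threshold
    )


def aggregate_blocks(
    blocks: Iterable[AlignmentBlock], size_threshold: int = SV_SIZE_THRESHOLD
) -> DivergenceDecomposition:
    """Sum per-block columns into a genome-wide decomposition."""
    m = mm = ind = large = 0
    for b in blocks:
        for op, ln in b.cigar:
            if op == "=":
                m += ln
            elif op == "X":
                mm += ln
            else:
                ind += ln
                if ln >= size_threshold:
                    large += ln
    return DivergenceDecomposition(m + mm + ind, m, mm, ind, large, size_threshold)


def cigar_block(cigar: Sequence[tuple[str, int]],
                query_chrom: str = "q", target_chrom: str = "t",
                strand: str = "+") -> AlignmentBlock:
    """Wrap a bare (op, length) run list as an AlignmentBlock at origin 0."""
    tspan = sum(ln for op, ln in cigar if op in "=XD")
    qspan = sum(ln for op, ln in cigar if op in "=XI")
    block = AlignmentBlock(query_chrom, 0, qspan, target_chrom, 0, tspan,
                           strand, tuple(cigar))
    block.validate()
    return block


def synteny_blocks(
    blocks: Iterable[AlignmentBlock], min_block: int = 1000
) -> pd.DataFrame:
    """Per-block coordinate/identity table for dot plots and ribbons.

    Blocks with target span >= min_block are emitted unmerged, one row
    each, in input order.
    """
    rows = []
    for b in blocks:
        if b.target_span < min_block:
            continue
        met = block_identity(b)
        rows.append(
            {
                "query_chrom": b.query_chrom,
                "query_start": b.query_start,
                "query_end": b.query_end,
                "target_chrom": b.target_chrom,
                "target_start": b.target_start,
                "target_end": b.target_end,
                "strand": b.strand,
                "length": b.target_span,
                "ide1": met.ide1,
                "ide2": met.ide2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "query_chrom", "query_start", "query_end",
            "target_chrom", "target_start", "target_end",
            "strand", "length", "ide1", "ide2",
        ],
    )


def block_metrics_table(blocks: Iterable[AlignmentBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        met = block_identity(b)
        rows.append(
            {
                "query_chrom": b.query_chrom,
                "target_chrom": b.target_chrom,
                "length": b.target_span,
                "columns": met.columns,
                "matches": met.matches,
                "mismatches": met.mismatches,
                "indel_bases": met.indel_bases,
                "gap_opens": met.gap_opens,
                "ide1": met.ide1,
                "ide2": met.ide2,
            }
        )
    return pd.DataFrame(rows)
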