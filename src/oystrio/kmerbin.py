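"""Trio binning: parent-unique k-mer sets and offspring read partitioning.

The procedure mirrors the classic trio-binning recipe: count canonical
k-mers in each parent, take the set difference with coverage-based count
bounds to get parent-unique sets (KLU_A, KLU_B), then assign each
offspring read by how many of its k-mers hit each unique set.  Long
accurate reads need at least two supporting unique k-mers; short reads
need one.  Reads without any unique k-mer are "common" and are placed
in both parental bins, so each bin contains everything compatible with
that parent.

K-mers are 2-bit encoded into uint64 (k <= 31) and stored as sorted
arrays; counting and membership are vectorized, so multi-megabase
genomes are practical in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

MAX_K = 31


class KmerError(ValueError):
    pass


def _seq_to_codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def encode_canonical(seq: str, k: int) -> np.ndarray:
    """Canonical (strand-collapsed) 2-bit codes of every valid k-mer window.

    Windows containing a non-ACGT character are skipped.  Canonical form
    is the lexicographic minimum of a k-mer and its reverse complement,
    which under the A<C<G<T = 0<1<2<3 encoding is the numeric minimum.
    """
    if k < 1:
        raise KmerError("k must be >= 1")
    if k > MAX_K:
        raise KmerError(f"k={k} exceeds the {MAX_K}-mer encoding limit")
    arr = _seq_to_codes(seq)
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    comp = np.where(arr < 4, 3 - arr, 0).astype(np.uint64)
    arr64 = arr.astype(np.uint64)
    for j in range(k):
        fwd = fwd * np.uint64(4) + arr64[j : j + n]
        valid &= arr[j : j + n] < 4
    for j in reversed(range(k)):
        rc = rc * np.uint64(4) + comp[j : j + n]
    canon = np.minimum(fwd, rc)
    return canon[valid]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical(kmer: str) -> str:
    from .synthio import revcomp

    rc = revcomp(kmer)
    return min(kmer, rc)


@dataclass
class KmerDB:
    """Canonical k-mer -> count map backed by sorted uint64 codes."""

    k: int
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, np.uint64))

    def __len__(self) -> int:
        return int(self.codes.size)

    def contains(self, queries: np.ndarray) -> np.ndarray:
        """Vectorized membership of query codes."""
        if self.codes.size == 0 or queries.size == 0:
            return np.zeros(queries.size, dtype=bool)
        idx = np.searchsorted(self.codes, queries)
        idx = np.minimum(idx, self.codes.size - 1)
        return self.codes[idx] == queries

    def to_dict(self) -> dict[str, int]:
        return {
            decode_kmer(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }

    @classmethod
    def from_dict(cls, mapping: Mapping[str, int], k: int | None = None) -> "KmerDB":
        if mapping:
            lengths = {len(s) for s in mapping}
            if len(lengths) != 1:
                raise KmerError("mixed k-mer lengths")
            k_inferred = lengths.pop()
            if k is not None and k != k_inferred:
                raise KmerError("k does not match k-mer length")
            k = k_inferred
        elif k is None:
            raise KmerError("k required for an empty database")
        codes = []
        for s, n in mapping.items():
            if canonical(s) != s:
                raise KmerError(f"k-mer {s!r} is not in canonical form")
            if n < 1:
                raise KmerError("counts must be >= 1")
            code = encode_canonical(s, k)
            if code.size != 1:
                raise KmerError(f"invalid k-mer {s!r}")
            codes.append((int(code[0]), int(n)))
        codes.sort()
        return cls(
            k,
            np.array([c for c, _ in codes], np.uint64),
            np.array([n for _, n in codes], np.uint64),
        )

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for c, n in zip(self.codes, self.counts):
                fh.write(f"{decode_kmer(int(c), self.k)}\t{int(n)}\n")

    @classmethod
    def read_tsv(cls, path: str, k: int | None = None) -> "KmerDB":
        mapping: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                kmer, n = line.rstrip("\n").split("\t")
                mapping[kmer] = int(n)
        return cls.from_dict(mapping, k)


@dataclass(frozen=True)
class BinningConfig:
    """Thresholds of the binning procedure.

    min_count/max_count bound the self-database counts after subtraction
    (excluding sequencing-error and high-copy-repeat k-mers); the
    defaults are the literal values used at ~90-100x parental coverage.
    ``for_coverage`` scales them as [0.3*coverage, 3*coverage].
    """

    k: int = 21
    min_count: int = 30
    max_count: int = 300
    min_support_long: int = 2
    min_support_short: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.min_count <= self.max_count):
            raise KmerError("need 1 <= min_count <= max_count")
        if self.min_support_long < 1 or self.min_support_short < 1:
            raise KmerError("min_support must be >= 1")

    @classmethod
    def for_coverage(cls, coverage: float, k: int = 21, **kw) -> "BinningConfig":
        return cls(
            k=k,
            min_count=max(1, int(round(0.3 * coverage))),
            max_count=max(1, int(round(3 * coverage))),
            **kw,
        )

    def min_support(self, read_type: str) -> int:
        if read_type == "long":
            return self.min_support_long
        if read_type == "short":
            return self.min_support_short
        raise KmerError(f"unknown read type {read_type!r}")


def build_kmer_db(sequences: Iterable[str], k: int) -> KmerDB:
    """Count canonical k-mers over all sequences, both strands collapsed."""
    chunks = [encode_canonical(seq, k) for seq in sequences]
    chunks = [c for c in chunks if c.size]
    if not chunks:
        warnings.warn(f"no sequence holds a {k}-mer; database is empty")
        return KmerDB(k)
    allc = np.concatenate(chunks)
    codes, counts = np.unique(allc, return_counts=True)
    return KmerDB(k, codes, counts.astype(np.uint64))


def unique_kmers(db_self: KmerDB, db_other: KmerDB, config: BinningConfig) -> KmerDB:
    """Presence-based set difference with count bounds on the retained side.

    Keeps k-mers of ``db_self`` that are absent from ``db_other`` (any
    count there disqualifies) and whose own count lies in
    [min_count, max_count].
    """
    if db_self.k != db_other.k:
        raise KmerError(f"k mismatch: {db_self.k} vs {db_other.k}")
    keep = ~db_other.contains(db_self.codes)
    keep &= (db_self.counts >= config.min_count) & (
        db_self.counts <= config.max_count
    )
    return KmerDB(db_self.k, db_self.codes[keep], db_self.counts[keep])


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    support_a: int
    support_b: int
    label: str                     # A | B | common | ambiguous


def _label(sa: int, sb: int, s: int) -> str:
    if sa >= s and sb >= s:
        return "ambiguous"
    if sa >= s and sb == 0:
        return "A"
    if sb >= s and sa == 0:
        return "B"
    return "common"


def classify_read(
    read_id: str,
    sequence: str,
    klu_a: KmerDB,
    klu_b: KmerDB,
    read_type: str,
    config: BinningConfig,
) -> ReadClassification:
    """Count parent-unique k-mer occurrences in a read and label it."""
    if klu_a.k != klu_b.k:
        raise KmerError("KLU databases disagree on k")
    s = config.min_support(read_type)
    if len(sequence) < klu_a.k:
        return ReadClassification(read_id, 0, 0, "common")
    codes = encode_canonical(sequence, klu_a.k)
    sa = int(klu_a.contains(codes).sum())
    sb = int(klu_b.contains(codes).sum())
    return ReadClassification(read_id, sa, sb, _label(sa, sb, s))


@dataclass
class PartitionReport:
    """Category tallies mirroring the partition-type barplot columns
    (parent-A-only, parent-B-only, no unique k-mer, both)."""

    n_reads: int
    n_a: int
    n_b: int
    n_common: int
    n_ambiguous: int

    @property
    def fractions(self) -> dict[str, float]:
        tot = max(self.n_reads, 1)
        return {
            "A": self.n_a / tot,
            "B": self.n_b / tot,
            "common": self.n_common / tot,
            "ambiguous": self.n_ambiguous / tot,
        }

    def to_tsv(self) -> str:
        fr = self.fractions
        lines = ["category\tcount\tfraction"]
        for key, n in (
            ("A", self.n_a),
            ("B", self.n_b),
            ("common", self.n_common),
            ("ambiguous", self.n_ambiguous),
        ):
            lines.append(f"{key}\t{n}\t{fr[key]:.6f}")
        return "\n".join(lines) + "\n"


@dataclass
class PartitionResult:
    classifications: list[ReadClassification]
    bin_a: list[str]               # read ids assigned to the A bin
    bin_b: list[str]
    report: PartitionReport


def partition_reads(
    reads: Iterable[tuple[str, str]],
    klu_a: KmerDB,
    klu_b: KmerDB,
    config: BinningConfig,
    read_type: str = "long",
) -> PartitionResult:
    """Partition offspring reads into parental bins.

    Bin A holds A-labelled reads, common reads and ambiguous reads whose
    majority support points to A; bin B symmetric.  Common reads (and
    support ties) go to both bins.
    """
    if len(klu_a) == 0 or len(klu_b) == 0:
        warnings.warn("a parent-unique k-mer set is empty; binning is degenerate")
    classes: list[ReadClassification] = []
    bin_a: list[str] = []
    bin_b: list[str] = []
    tally = {"A": 0, "B": 0, "common": 0, "ambiguous": 0}
    for rid, seq in reads:
        rc = classify_read(rid, seq, klu_a, klu_b, read_type, config)
        classes.append(rc)
        tally[rc.label] += 1
        label = rc.label
        if label == "ambiguous":   # resolve by majority support; tie -> common
            if rc.support_a > rc.support_b:
                label = "A"
            elif rc.support_b > rc.support_a:
                label = "B"
            else:
                label = "common"
        if label == "A":
            bin_a.append(rid)
        elif label == "B":
            bin_b.append(rid)
        else:
            bin_a.append(rid)
            bin_b.append(rid)
    report = PartitionReport(
        len(classes), tally["A"], tally["B"], tally["common"], tally["ambiguous"]
    )
    return PartitionResult(classes, bin_a, bin_b, report)
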