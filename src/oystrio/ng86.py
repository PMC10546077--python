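"""Nei–Gojobori (1986) Ka/Ks estimation.

Counts synonymous (S) and nonsynonymous (N) sites per codon as the
fraction of the three possible single-base changes at each position
that preserve the encoded amino acid (changes creating stop codons
count as nonsynonymous), averaged over the two sequences.  Observed
differences in multi-hit codons are averaged over all minimal
mutational pathways; pathways passing through a stop codon are
discarded and the remaining weights renormalized (if every pathway
hits a stop, all are kept).  Proportions are Jukes–Cantor corrected,
d = -3/4 ln(1 - 4p/3), and significance of Ka/Ks != 1 is assessed with
a Fisher exact test on the rounded substitution-vs-site 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from scipy.stats import fisher_exact

_BASES = "TCAG"
_CODON_AA: dict[str, str] = {}
_AA_TABLE = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    _CODON_AA[_b1 + _b2 + _b3] = _AA_TABLE[_i]

STOP = "*"


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter; '*' for stop) of an unambiguous codon."""
    return _CODON_AA[codon.upper().replace("U", "T")]


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible
    changes that are synonymous; the three positions sum to 3.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if translate_codon(mutant) == aa and aa != STOP:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two codons,
    averaged over minimal mutational pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths: list[tuple[float, float, bool]] = []  # (syn, nonsyn, hits_stop)
    for order in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0.0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nonsyn += 1
            if translate_codon(nxt) == STOP and nxt != c2:
                hits_stop = True
            cur = nxt
        paths.append((syn, nonsyn, hits_stop))
    usable = [p for p in paths if not p[2]] or paths
    syn = sum(p[0] for p in usable) / len(usable)
    nonsyn = sum(p[1] for p in usable) / len(usable)
    return syn, nonsyn


@dataclass(frozen=True)
class KaKsResult:
    S: float                     # synonymous sites (two-sequence average)
    N: float                     # nonsynonymous sites
    Sd: float                    # observed synonymous substitutions
    Nd: float
    ps: float
    pn: float
    ks: float | None             # None when the JC correction is undefined
    ka: float | None
    ratio: float | None          # None when Ks is 0 or undefined
    p_value: float
    n_codons: int


def _jukes_cantor(p: float) -> float | None:
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0.0:
        return None
    return -0.75 * math.log(x)


_AMBIGUOUS = set("NRYSWKMBDHV-")


def kaks_ng86(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka/Ks for a gap-free pair of in-frame coding sequences.

    Codons containing ambiguity characters in either sequence are
    skipped; internal stop codons are rejected.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences differ in length")
    if len(cds_a) % 3:
        raise ValueError("coding sequence length is not a multiple of 3")
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca) & _AMBIGUOUS or set(cb) & _AMBIGUOUS:
            continue
        is_last = i == len(a) - 3
        if (translate_codon(ca) == STOP or translate_codon(cb) == STOP):
            if is_last:
                continue      # terminal stop codon, not part of the ORF proper
            raise ValueError(f"internal stop codon at position {i}")
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = codon_path_differences(ca, cb)
        Sd += ds
        Nd += dn
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no scorable codons")
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    table = [
        [round(Sd), max(0, round(S - Sd))],
        [round(Nd), max(0, round(N - Nd))],
    ]
    _, p = fisher_exact(table)
    return KaKsResult(S, N, Sd, Nd, ps, pn, ks, ka, ratio, float(p), n_codons)
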