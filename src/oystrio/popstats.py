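"""Population divergence statistics from diploid genotypes.

SNP filtering (biallelic, MAF > 0.01, missing rate < 0.05), allele
frequency classification (species-enriched |dp| > 0.75, species-specific
|dp| > 0.95), windowed nucleotide diversity and Weir–Cockerham (1984)
Fst, a joint Fst/pi-ratio selection scan on empirical quantile tails,
and linkage-disequilibrium decay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

MIN_CALLED_HAPLOTYPES = 4
ENRICHED_THRESHOLD = 0.75
SPECIFIC_THRESHOLD = 0.95


@dataclass(frozen=True)
class FilterConfig:
    min_maf: float = 0.01          # strict >
    max_missing: float = 0.05      # strict <

    def __post_init__(self) -> None:
        if not (0 <= self.min_maf <= 1 and 0 <= self.max_missing <= 1):
            raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes: alt-allele dosage per site x sample, -1 missing."""

    samples: list[str]
    chrom: np.ndarray              # (n_sites,) str
    pos: np.ndarray                # (n_sites,) int, 1-based
    dosage: np.ndarray             # (n_sites, n_samples) int8, -1 = missing

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(n) for n in names]
        return GenotypeMatrix(
            list(names), self.chrom, self.pos, self.dosage[:, idx]
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples, self.chrom[mask], self.pos[mask], self.dosage[mask]
        )


def read_vcf(path: str) -> GenotypeMatrix:
    """Load biallelic-compatible GT dosages from a VCF (cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms, poss, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            # keep multi-allelic records as placeholders so filtering
            # decisions stay in filter_snps; encode as all-missing
            rows.append(np.full(len(samples), -2, np.int8))
        else:
            gt = var.gt_types.astype(np.int8)   # 0,1,2; 3 = unknown
            gt[gt == 3] = -1
            rows.append(gt)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not rows:
        raise ValueError("VCF holds no records with GT fields")
    return GenotypeMatrix(
        samples,
        np.array(chroms),
        np.array(poss, dtype=np.int64),
        np.vstack(rows),
    )


def allele_frequencies(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt frequency, called haplotypes) per site, ignoring missing."""
    called = dosage >= 0
    n_hap = 2 * called.sum(axis=1)
    alt = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_hap > 0, alt / np.maximum(n_hap, 1), np.nan)
    return p, n_hap


def filter_snps(gm: GenotypeMatrix, config: FilterConfig = FilterConfig()) -> GenotypeMatrix:
    """Biallelic sites with MAF strictly above and missing rate strictly
    below the configured thresholds, computed over all samples."""
    biallelic = ~(gm.dosage == -2).any(axis=1)
    missing_rate = (gm.dosage == -1).sum(axis=1) / len(gm.samples)
    p, n_hap = allele_frequencies(np.where(gm.dosage < 0, -1, gm.dosage))
    maf = np.minimum(p, 1 - p)
    keep = (
        biallelic
        & (missing_rate < config.max_missing)
        & (n_hap > 0)
        & (maf > config.min_maf)
    )
    return gm.subset_sites(keep)


@dataclass
class SnpClassification:
    delta: np.ndarray
    snp_class: np.ndarray          # none | enriched | specific
    proportions: pd.DataFrame | None = None
    chi2: tuple[float, float] | None = None


def classify_snps(
    gm: GenotypeMatrix,
    populations: Mapping[str, Sequence[str]],
    annotations: Sequence[str] | None = None,
) -> SnpClassification:
    """Classify SNPs by between-population allele-frequency difference.

    |dp| > 0.75 -> enriched, > 0.95 -> specific (strict; specific implies
    enriched).  With per-SNP annotation categories, per-category class
    proportions and a chi-square homogeneity test are added.
    """
    (pop_a, pop_b) = sorted(populations)
    p_a, _ = allele_frequencies(gm.subset_samples(populations[pop_a]).dosage)
    p_b, _ = allele_frequencies(gm.subset_samples(populations[pop_b]).dosage)
    delta = np.abs(p_a - p_b)
    snp_class = np.where(
        delta > SPECIFIC_THRESHOLD,
        "specific",
        np.where(delta > ENRICHED_THRESHOLD, "enriched", "none"),
    )
    result = SnpClassification(delta, snp_class)
    if annotations is not None:
        ann = np.asarray(annotations)
        cats = sorted(set(ann))
        rows = []
        for cat in cats:
            mask = ann == cat
            n = int(mask.sum())
            n_enr = int((snp_class[mask] != "none").sum())
            n_spec = int((snp_class[mask] == "specific").sum())
            rows.append(
                {
                    "category": cat,
                    "n_snps": n,
                    "enriched": n_enr,
                    "specific": n_spec,
                    "prop_enriched": n_enr / n if n else np.nan,
                    "prop_specific": n_spec / n if n else np.nan,
                }
            )
        props = pd.DataFrame(rows)
        usable = props[props["n_snps"] > 0]
        if len(usable) < len(props):
            warnings.warn("empty annotation categories excluded from the test")
        if len(usable) >= 2 and usable["enriched"].sum() > 0:
            table = np.array(
                [usable["enriched"], usable["n_snps"] - usable["enriched"]]
            )
            chi2, p, _, _ = stats.chi2_contingency(table)
            result.chi2 = (float(chi2), float(p))
        result.proportions = props
    return result


def _windows_for(chrom_pos: np.ndarray, window: int) -> np.ndarray:
    return (chrom_pos - 1) // window


def per_site_pi(dosage: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2c(n-c)/(n(n-1)) over called
    haplotypes; sites with fewer than 4 called haplotypes give NaN."""
    called = dosage >= 0
    n = 2 * called.sum(axis=1)
    c = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c * (n - c) / (n * (n - 1.0))
    pi[n < MIN_CALLED_HAPLOTYPES] = np.nan
    return pi


def window_pi(
    gm: GenotypeMatrix,
    populations: Mapping[str, Sequence[str]],
    window: int = 10_000,
) -> pd.DataFrame:
    """Nucleotide diversity per window per population (per-bp, full
    window length as denominator, invariant sites counted as zero)."""
    frames = []
    for pop, samples in sorted(populations.items()):
        sub = gm.subset_samples(samples)
        pi = per_site_pi(sub.dosage)
        df = pd.DataFrame(
            {"chrom": gm.chrom, "win": _windows_for(gm.pos, window), "pi": pi}
        )
        agg = df.groupby(["chrom", "win"], observed=True)["pi"].sum(min_count=1)
        agg = (agg / window).rename(f"pi_{pop}")
        frames.append(agg)
    out = pd.concat(frames, axis=1).reset_index()
    out["start"] = out["win"] * window
    out["end"] = out["start"] + window
    return out.drop(columns="win")[
        ["chrom", "start", "end"] + [c for c in out.columns if c.startswith("pi_")]
    ]


def wc_fst_components(
    dosage_a: np.ndarray, dosage_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) variance components for two
    populations of diploids: (a, a+b+c).  Sites with too few called
    haplotypes in either population come back NaN."""
    comps = []
    for dos in (dosage_a, dosage_b):
        called = dos >= 0
        n_i = called.sum(axis=1).astype(float)            # diploid individuals
        c_i = np.where(called, dos, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = c_i / (2 * n_i)
        h_i = np.where(called, dos == 1, False).sum(axis=1) / np.maximum(n_i, 1)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    denom = a + b + c
    bad = (2 * n1 < MIN_CALLED_HAPLOTYPES) | (2 * n2 < MIN_CALLED_HAPLOTYPES)
    a = np.where(bad, np.nan, a)
    denom = np.where(bad, np.nan, denom)
    return a, denom


def window_fst(
    gm: GenotypeMatrix,
    populations: Mapping[str, Sequence[str]],
    window: int = 10_000,
) -> pd.DataFrame:
    """Weighted (ratio-of-sums) Weir–Cockerham Fst per window.

    Negative estimates are reported as-is; windows without usable sites
    come back NaN.
    """
    if len(populations) != 2:
        raise ValueError("exactly two populations required")
    (pa, pb) = sorted(populations)
    dos_a = gm.subset_samples(populations[pa]).dosage
    dos_b = gm.subset_samples(populations[pb]).dosage
    a, denom = wc_fst_components(dos_a, dos_b)
    df = pd.DataFrame(
        {"chrom": gm.chrom, "win": _windows_for(gm.pos, window), "a": a, "d": denom}
    )
    agg = df.groupby(["chrom", "win"], observed=True)[["a", "d"]].sum(min_count=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["fst"] = agg["a"] / agg["d"]
    agg = agg.reset_index()
    agg["start"] = agg["win"] * window
    agg["end"] = agg["start"] + window
    return agg[["chrom", "start", "end", "fst"]]


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank empirical quantile on the sorted finite values."""
    finite = np.sort(values[np.isfinite(values)])
    if finite.size == 0:
        raise ValueError("no finite values")
    rank = max(1, math.ceil(q * finite.size))
    return float(finite[rank - 1])


@dataclass
class SelectionScan:
    windows: pd.DataFrame
    fst_threshold: float
    ratio_low: float
    ratio_high: float
    candidate_genes: list[str] = field(default_factory=list)


def selection_scan(
    windows: pd.DataFrame,
    pi_a: str,
    pi_b: str,
    fst_quantile: float = 0.95,
    ratio_quantiles: tuple[float, float] = (0.05, 0.95),
    gene_models: Mapping[str, object] | None = None,
) -> SelectionScan:
    """Joint Fst / pi-ratio outlier scan.

    Thresholds are empirical nearest-rank quantiles of the finite window
    values; comparisons against them are strict.  A window is a
    candidate when its Fst exceeds the top quantile AND its pi ratio
    falls in either tail.  With gene models, genes overlapping any
    candidate window (any bp) are collected once each.
    """
    win = windows.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        win["pi_ratio"] = win[pi_a] / win[pi_b]
    finite = win[np.isfinite(win["fst"]) & np.isfinite(win["pi_ratio"])]
    if len(finite) < 20:
        warnings.warn("fewer than 20 usable windows; quantiles are unstable")
    fst_thr = nearest_rank_quantile(finite["fst"].to_numpy(), fst_quantile)
    lo_thr = nearest_rank_quantile(finite["pi_ratio"].to_numpy(), ratio_quantiles[0])
    hi_thr = nearest_rank_quantile(finite["pi_ratio"].to_numpy(), ratio_quantiles[1])
    win["high_fst"] = win["fst"] > fst_thr
    win["low_ratio_tail"] = win["pi_ratio"] < lo_thr
    win["high_ratio_tail"] = win["pi_ratio"] > hi_thr
    win["candidate"] = win["high_fst"] & (
        win["low_ratio_tail"] | win["high_ratio_tail"]
    )
    # ratio tail orientation names the putatively selected species
    win["selected_pop"] = np.where(
        ~win["candidate"], "",
        np.where(win["low_ratio_tail"], pi_a.split("_", 1)[1], pi_b.split("_", 1)[1]),
    )
    genes: list[str] = []
    if gene_models is not None:
        trees: dict[str, IntervalTree] = {}
        for _, row in win[win["candidate"]].iterrows():
            trees.setdefault(row["chrom"], IntervalTree()).addi(
                row["start"], row["end"]
            )
        seen = set()
        for gid, model in gene_models.items():
            tree = trees.get(model.chrom)
            if tree is None:
                continue
            if tree.overlap(model.gene_start, model.gene_end) and gid not in seen:
                seen.add(gid)
                genes.append(gid)
    return SelectionScan(win, fst_thr, lo_thr, hi_thr, genes)


def ld_decay(
    gm: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    max_dist: int = 5000,
    bin_width: int = 100,
) -> pd.DataFrame:
    """Mean pairwise r^2 per distance bin.

    r^2 is the squared Pearson correlation of alt-allele dosages over
    samples called at both sites; monomorphic members and zero-distance
    pairs are skipped.  Bins are (0, bin_width], (bin_width, 2*bin_width]...
    """
    sub = gm if samples is None else gm.subset_samples(samples)
    n_bins = math.ceil(max_dist / bin_width)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom in np.unique(sub.chrom):
        mask = sub.chrom == chrom
        pos = sub.pos[mask]
        dos = sub.dosage[mask].astype(float)
        dos[dos < 0] = np.nan
        order = np.argsort(pos)
        pos, dos = pos[order], dos[order]
        n = pos.size
        for i in range(n - 1):
            j = i + 1
            while j < n and pos[j] - pos[i] <= max_dist:
                d = int(pos[j] - pos[i])
                if d > 0:
                    both = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
                    x, y = dos[i][both], dos[j][both]
                    if x.size >= 2 and np.std(x) > 0 and np.std(y) > 0:
                        r = np.corrcoef(x, y)[0, 1]
                        b = (d - 1) // bin_width
                        sums[b] += r * r
                        counts[b] += 1
                j += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "dist_low": np.arange(n_bins) * bin_width,
            "dist_high": (np.arange(n_bins) + 1) * bin_width,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )
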