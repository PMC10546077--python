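"""Population statistics tests: filtering boundaries, SNP classes, pi and
Weir–Cockerham Fst with independent scalar oracles, selection scan, LD."""

import numpy as np
import pandas as pd
import pytest

from oystrio import popstats, synthio
from oystrio.popstats import (
    FilterConfig,
    GenotypeMatrix,
    allele_frequencies,
    classify_snps,
    filter_snps,
    ld_decay,
    nearest_rank_quantile,
    per_site_pi,
    selection_scan,
    wc_fst_components,
    window_fst,
    window_pi,
)


def _gm(dosage, pos=None, samples=None, chrom="c"):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    return GenotypeMatrix(
        samples or [f"s{i}" for i in range(n_samples)],
        np.array([chrom] * n_sites),
        np.asarray(pos if pos is not None else np.arange(1, n_sites + 1),
                   dtype=np.int64),
        dosage,
    )


# ----------------------------------------------------------- oracles


def oracle_wc_site(dos_a, dos_b):
    """Scalar Weir–Cockerham (1984) components for one site, two pops."""
    def summarize(d):
        called = [x for x in d if x >= 0]
        n = len(called)
        p = sum(called) / (2 * n)
        h = sum(1 for x in called if x == 1) / n
        return n, p, h

    (n1, p1, h1), (n2, p2, h2) = summarize(dos_a), summarize(dos_b)
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, a + b + c


def oracle_pi_window(dosage, window):
    """Direct per-site averaging: sum over sites of mean pairwise
    difference probability among called haplotypes, over window length."""
    total = 0.0
    for site in dosage:
        called = [int(x) for x in site if x >= 0]
        n = 2 * len(called)
        if n < 4:
            continue
        c = sum(called)
        total += 2 * c * (n - c) / (n * (n - 1))
    return total / window


# ----------------------------------------------------------- filtering


class TestFilter:
    def test_maf_boundary_strict(self):
        # 200 haplotypes: alt counts 1 (MAF 0.005), 2 (0.01), 4 (0.02)
        n = 100
        dosage = np.zeros((3, n), np.int8)
        dosage[0, 0] = 1
        dosage[1, :2] = 1
        dosage[2, :4] = 1
        out = filter_snps(_gm(dosage))
        assert list(out.pos) == [3]

    def test_toy_maf_set(self):
        # MAFs {0.005, 0.01, 0.02, 0.3, 0.5} over 100 samples -> 3 retained
        n = 100
        dosage = np.zeros((5, n), np.int8)
        for row, alt in enumerate((1, 2, 4, 60, 100)):
            full, rem = divmod(alt, 2)
            dosage[row, :full] = 2
            if rem:
                dosage[row, full] = 1
        out = filter_snps(_gm(dosage))
        assert out.n_sites == 3
        assert list(out.pos) == [3, 4, 5]

    def test_missing_rate_strict(self):
        n = 20                      # one missing genotype = rate 0.05
        dosage = np.tile(np.array([[1] + [0] * (n - 1)], np.int8), (2, 1))
        dosage[1, -1] = -1
        out = filter_snps(_gm(dosage))
        assert list(out.pos) == [1]

    def test_triallelic_removed(self, tmp_path):
        vcf = "\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=c,length=1000>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
            "c\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1",
            "c\t20\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t1/2",
        ]) + "\n"
        p = tmp_path / "t.vcf"
        p.write_text(vcf)
        gm = popstats.read_vcf(str(p))
        assert gm.n_sites == 2
        out = filter_snps(gm)
        assert list(out.pos) == [10]

    def test_bad_config(self):
        with pytest.raises(ValueError):
            FilterConfig(min_maf=-0.1)


# ----------------------------------------------------------- classify


class TestClassify:
    def _two_pop_gm(self, p_a, p_b, n=50, seed=0):
        rng = np.random.default_rng(seed)
        sites = len(p_a)
        dos_a = rng.binomial(2, np.asarray(p_a)[:, None], (sites, n))
        dos_b = rng.binomial(2, np.asarray(p_b)[:, None], (sites, n))
        gm = _gm(np.hstack([dos_a, dos_b]),
                 samples=[f"a{i}" for i in range(n)]
                 + [f"b{i}" for i in range(n)])
        pops = {"A": gm.samples[:n], "B": gm.samples[n:]}
        return gm, pops

    def test_delta_096_specific(self):
        dos_a = np.zeros((1, 50), np.int8)
        dos_b = np.zeros((1, 50), np.int8)
        dos_b[0, :48] = 2           # p_b = 0.96
        gm = _gm(np.hstack([dos_a, dos_b]),
                 samples=[f"a{i}" for i in range(50)]
                 + [f"b{i}" for i in range(50)])
        cls = classify_snps(gm, {"A": gm.samples[:50], "B": gm.samples[50:]})
        assert cls.delta[0] == pytest.approx(0.96)
        assert cls.snp_class[0] == "specific"

    def test_delta_075_exactly_none(self):
        dos_a = np.zeros((1, 50), np.int8)
        dos_b = np.zeros((1, 50), np.int8)
        dos_b[0, :37] = 2
        dos_b[0, 37] = 1            # p_b = 75/100 = 0.75 exactly
        gm = _gm(np.hstack([dos_a, dos_b]),
                 samples=[f"a{i}" for i in range(50)]
                 + [f"b{i}" for i in range(50)])
        cls = classify_snps(gm, {"A": gm.samples[:50], "B": gm.samples[50:]})
        assert cls.delta[0] == pytest.approx(0.75)
        assert cls.snp_class[0] == "none"

    def test_specific_implies_enriched(self):
        rng = np.random.default_rng(2)
        p_a = rng.uniform(0, 1, 200)
        p_b = rng.uniform(0, 1, 200)
        gm, pops = self._two_pop_gm(p_a, p_b, seed=3)
        cls = classify_snps(gm, pops)
        specific = cls.snp_class == "specific"
        assert (cls.delta[specific] > 0.95).all()
        # every specific site also satisfies the enriched threshold
        assert (cls.delta[cls.snp_class == "enriched"] > 0.75).all()

    def test_annotation_proportions_and_chi2(self):
        p_a = [0.0] * 10 + [0.5] * 10
        p_b = [1.0] * 10 + [0.5] * 10
        gm, pops = self._two_pop_gm(p_a, p_b, n=40, seed=4)
        ann = ["nonsynonymous"] * 10 + ["intergenic"] * 10
        cls = classify_snps(gm, pops, annotations=ann)
        props = cls.proportions.set_index("category")
        assert props.loc["nonsynonymous", "prop_specific"] > 0.8
        assert props.loc["intergenic", "prop_specific"] < 0.2
        chi2, p = cls.chi2
        assert p < 0.01

    def test_planted_specific_recovery(self):
        vcf_text, _popmap, truth = synthio.simulate_population_vcf(
            69, 86, 2000, 0.05, seed=42
        )
        # parse the generated VCF text without touching disk
        lines = [l for l in vcf_text.splitlines() if not l.startswith("#")]
        header = [l for l in vcf_text.splitlines()
                  if l.startswith("#CHROM")][0].split("\t")
        samples = header[9:]
        code = {"0/0": 0, "0/1": 1, "1/1": 2}
        dosage = np.array(
            [[code[g] for g in l.split("\t")[9:]] for l in lines], np.int8
        )
        pos = np.array([int(l.split("\t")[1]) for l in lines])
        gm = _gm(dosage, pos=pos, samples=samples)
        gm = filter_snps(gm)
        pops = {"A": samples[:69], "B": samples[69:]}
        cls = classify_snps(gm, pops)
        planted_pos = 100 * (truth.planted_specific + 1)
        mask = np.isin(gm.pos, planted_pos)
        assert mask.sum() == len(planted_pos), "planted sites lost in filtering"
        recovered = (cls.snp_class[mask] == "specific").mean()
        assert recovered >= 0.95


# ----------------------------------------------------------- diversity


class TestPi:
    def test_hand_example(self):
        # 4 haplotypes, one SNP with c = 2, window 10 bp
        gm = _gm([[1, 1]], pos=[5])
        out = window_pi(gm, {"P": gm.samples}, window=10)
        assert out.loc[0, "pi_P"] == pytest.approx((2 * 2 * 2 / 12) / 10)

    def test_window_length_in_denominator(self):
        gm = _gm([[1, 1]], pos=[5])
        out10 = window_pi(gm, {"P": gm.samples}, window=10)
        out20 = window_pi(gm, {"P": gm.samples}, window=20)
        assert out20.loc[0, "pi_P"] == pytest.approx(
            out10.loc[0, "pi_P"] / 2
        )

    def test_monomorphic_zero(self):
        gm = _gm([[0, 0], [2, 2]], pos=[1, 2])
        out = window_pi(gm, {"P": gm.samples}, window=10)
        assert out.loc[0, "pi_P"] == 0.0

    def test_too_few_haplotypes_nan(self):
        pi = per_site_pi(np.array([[1, -1]], np.int8))
        assert np.isnan(pi[0])

    def test_matches_direct_averaging_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n_sites = int(rng.integers(1, 100))
            dosage = rng.integers(-1, 3, size=(n_sites, 8)).astype(np.int8)
            gm = _gm(dosage, pos=rng.choice(
                np.arange(1, 1001), size=n_sites, replace=False))
            out = window_pi(gm, {"P": gm.samples}, window=1000)
            want = oracle_pi_window(dosage, 1000)
            assert out.loc[0, "pi_P"] == pytest.approx(want, abs=1e-12)


# ----------------------------------------------------------- fst


class TestFst:
    def test_fixed_difference_is_one(self):
        dos_a = np.zeros((1, 10), np.int8)
        dos_b = np.full((1, 10), 2, np.int8)
        a, d = wc_fst_components(dos_a, dos_b)
        assert a[0] / d[0] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
        a, d = wc_fst_components(dos, dos)
        fst = np.nansum(a) / np.nansum(d)
        assert fst <= 0.0 + 1e-12

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            sites = int(rng.integers(1, 5))
            dos_a = rng.integers(0, 3, (sites, n1)).astype(np.int8)
            dos_b = rng.integers(0, 3, (sites, n2)).astype(np.int8)
            a, d = wc_fst_components(dos_a, dos_b)
            for s in range(sites):
                oa, od = oracle_wc_site(dos_a[s], dos_b[s])
                assert a[s] == pytest.approx(oa, abs=1e-12)
                assert d[s] == pytest.approx(od, abs=1e-12)

    def test_window_ratio_of_sums(self):
        dos_a = np.array([[0] * 10, [1] * 10], np.int8)
        dos_b = np.array([[2] * 10, [1] * 10], np.int8)
        gm = _gm(np.hstack([dos_a, dos_b]), pos=[5, 6],
                 samples=[f"a{i}" for i in range(10)]
                 + [f"b{i}" for i in range(10)])
        pops = {"A": gm.samples[:10], "B": gm.samples[10:]}
        out = window_fst(gm, pops, window=100)
        a, d = wc_fst_components(dos_a, dos_b)
        assert out.loc[0, "fst"] == pytest.approx(a.sum() / d.sum())

    def test_two_populations_required(self):
        gm = _gm([[1, 1]], pos=[1])
        with pytest.raises(ValueError):
            window_fst(gm, {"A": ["s0"]}, window=10)


# ----------------------------------------------------------- scan


class TestSelectionScan:
    def _windows(self):
        rows = []
        for i in range(999):
            if i < 100:
                ratio = 0.1
            elif i < 200:
                ratio = 3.0
            else:
                ratio = 1.0
            rows.append(("c", i * 10, i * 10 + 10, 0.5 * i / 999, ratio))
        rows.append(("c", 9990, 10000, 0.9, 0.01))   # the planted window
        df = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "fst", "pi_ratio_raw"]
        )
        df["pi_A"] = df["pi_ratio_raw"] * 1e-3
        df["pi_B"] = 1e-3
        return df.drop(columns="pi_ratio_raw")

    def test_planted_outlier_exactly_flagged(self):
        scan = selection_scan(self._windows(), "pi_A", "pi_B")
        cand = scan.windows[scan.windows["candidate"]]
        assert list(cand["start"]) == [9990]
        assert cand.iloc[0]["selected_pop"] == "A"

    def test_all_identical_no_candidates(self):
        df = pd.DataFrame(
            {"chrom": ["c"] * 30, "start": range(30), "end": range(1, 31),
             "fst": 0.1, "pi_A": 1e-3, "pi_B": 1e-3}
        )
        scan = selection_scan(df, "pi_A", "pi_B")
        assert not scan.windows["candidate"].any()

    def test_gene_overlapping_two_windows_counted_once(self):
        class Model:
            chrom, gene_start, gene_end = "c", 9_985, 10_000

        windows = self._windows()
        # add a second planted candidate window adjacent to the first
        windows.loc[len(windows)] = ["c", 9_980, 9_990, 0.95, 0.01 * 1e-3,
                                     1e-3]
        scan = selection_scan(windows, "pi_A", "pi_B",
                              gene_models={"g1": Model()})
        assert scan.windows["candidate"].sum() == 2
        assert scan.candidate_genes == ["g1"]

    def test_few_windows_warn(self):
        df = pd.DataFrame(
            {"chrom": ["c"] * 5, "start": range(5), "end": range(1, 6),
             "fst": np.linspace(0, 1, 5), "pi_A": 1e-3, "pi_B": 1e-3}
        )
        with pytest.warns(UserWarning):
            selection_scan(df, "pi_A", "pi_B")

    def test_nearest_rank_quantile(self):
        values = np.arange(1.0, 101.0)
        assert nearest_rank_quantile(values, 0.95) == 95.0
        assert nearest_rank_quantile(values, 0.05) == 5.0
        with pytest.raises(ValueError):
            nearest_rank_quantile(np.array([np.nan]), 0.5)


# ----------------------------------------------------------- LD


class TestLdDecay:
    def test_perfect_pair(self):
        gm = _gm([[0, 1, 2, 1], [0, 1, 2, 1]], pos=[10, 60])
        out = ld_decay(gm, max_dist=500, bin_width=100)
        assert out.loc[0, "mean_r2"] == pytest.approx(1.0)
        assert out.loc[0, "n_pairs"] == 1

    def test_zero_distance_pair_excluded(self):
        gm = _gm([[0, 1, 2, 1], [0, 1, 2, 1]], pos=[10, 10])
        out = ld_decay(gm, max_dist=500, bin_width=100)
        assert out["n_pairs"].sum() == 0

    def test_independent_sites_near_sampling_floor(self):
        rng = np.random.default_rng(77)
        n, sites = 50, 120
        dosage = rng.binomial(2, 0.5, size=(sites, n)).astype(np.int8)
        gm = _gm(dosage, pos=np.arange(1, sites + 1) * 3)
        out = ld_decay(gm, max_dist=400, bin_width=400)
        mean_r2 = out.loc[0, "mean_r2"]
        # expectation for unlinked sites is ~1/(n-1)
        assert 0.2 / n < mean_r2 < 4.0 / n

    def test_bins_cover_range(self):
        gm = _gm([[0, 1, 2, 1], [0, 1, 2, 1]], pos=[10, 60])
        out = ld_decay(gm, max_dist=1000, bin_width=250)
        assert list(out["dist_low"]) == [0, 250, 500, 750]
        assert list(out["dist_high"]) == [250, 500, 750, 1000]
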