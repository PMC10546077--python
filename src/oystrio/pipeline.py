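"""End-to-end orchestration of the simulated trio analysis.

A run configuration (YAML or dict) selects stages and parameters; the
pipeline executes them in dependency order (sim -> bin -> aln -> ortho
-> domains -> pop -> stats), writes each stage's outputs plus a JSON
summary into a run directory, and records a manifest with the seed and
a checksum per output file so that deterministic stages can be audited
for byte-identical reproduction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import alnmetrics, asmstats, domexp, kmerbin, popstats, synthio

log = logging.getLogger("oystrio")

ALL_STAGES = ("sim", "bin", "aln", "ortho", "domains", "pop", "stats")
DEFAULT_EXON_DIST = {1: 0.14, 3: 0.35, 6: 0.29, 12: 0.16, 22: 0.06}


@dataclasses.dataclass
class RunConfig:
    seed: int = 42
    outdir: str = "oystrio_run"
    stages: tuple[str, ...] = ALL_STAGES
    genome_length: int = 300_000
    n_genes: int = 40
    substitution_rate: float = 0.01
    coverage_long: float = 3.0
    coverage_short: float = 0.0
    long_read_length_mean: int = 12_000
    k: int = 21
    n_individuals: tuple[int, int] = (30, 30)
    n_snp_sites: int = 2_000
    fraction_differentiated: float = 0.02
    window: int = 10_000
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "n_individuals" in data:
            data["n_individuals"] = tuple(data["n_individuals"])
        return cls(**data)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


class DependencyError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the selected stages; returns the run directory."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict[str, Any] = {}
    summary: dict[str, Any] = {}
    stages = [s for s in ALL_STAGES if s in config.stages]
    for stage in stages:
        log.info("stage %s", stage)
        _STAGE_FUNCS[stage](config, out, state, summary)
        with open(out / f"{stage}.summary.json", "w") as fh:
            json.dump(summary.get(stage, {}), fh, indent=2, default=str)
    manifest = {
        "seed": config.seed,
        "stages": stages,
        "config": dataclasses.asdict(config),
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def _require(state: Mapping[str, Any], key: str, stage: str, needed_by: str) -> Any:
    if key not in state:
        raise DependencyError(
            f"stage {needed_by!r} needs output of stage {stage!r}; "
            "enable it or provide inputs explicitly"
        )
    return state[key]


def _stage_sim(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    cfg = synthio.SimConfig(
        seed=config.seed,
        genome_length=config.genome_length,
        substitution_rate=config.substitution_rate,
        long_read_length_mean=config.long_read_length_mean,
        coverage_long=config.coverage_long,
        coverage_short=config.coverage_short,
    )
    rng = np.random.default_rng(cfg.seed)
    ancestor = synthio.random_genome(cfg.genome_length, rng)
    genes = synthio.simulate_gene_models(
        cfg.genome_length, config.n_genes, DEFAULT_EXON_DIST, cfg.seed, "anc", "g"
    )
    ancestor = synthio.sanitize_orfs(ancestor, genes)
    cds = [seg for g in genes for seg in g.cds_segments]
    genome_a, genome_b, truth = synthio.evolve_pair(ancestor, cfg, cds)
    trio, truth = synthio.make_trio(genome_a, genome_b, cfg, truth)
    reads, truth = synthio.simulate_reads(trio.offspring, truth, cfg)
    gff_a, gff_b, ortho = synthio.simulate_ortholog_annotations(
        len(ancestor), truth, config.n_genes, DEFAULT_EXON_DIST, cfg.seed,
        genes=genes,
    )
    vcf_text, popmap, pop_truth = synthio.simulate_population_vcf(
        *config.n_individuals,
        config.n_snp_sites,
        config.fraction_differentiated,
        seed=cfg.seed,
        vcf_path=str(out / "population.vcf"),
        popmap_path=str(out / "popmap.tsv"),
    )
    synthio.write_fasta([("chrA1", genome_a)], str(out / "genomeA.fasta"))
    synthio.write_fasta([("chrB1", genome_b)], str(out / "genomeB.fasta"))
    synthio.write_fastq(reads.long_reads, str(out / "offspring_long.fastq"))
    (out / "genomeA.gff3").write_text(gff_a)
    (out / "genomeB.gff3").write_text(gff_b)
    ortho.to_csv(out / "orthogroups.tsv", sep="\t", index=False)
    state.update(
        sim_cfg=cfg, trio=trio, truth=truth, reads=reads,
        genomes={"A": genome_a, "B": genome_b},
        gff={"A": gff_a, "B": gff_b}, ortho=ortho, pop_truth=pop_truth,
    )
    summary["sim"] = {
        "genome_length": cfg.genome_length,
        "n_long_reads": len(reads.long_reads),
        "n_variants": len(truth.planted_variants),
        "n_genes": len(ortho) // 2,
        "n_snp_sites": config.n_snp_sites,
    }


def _stage_bin(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    trio = _require(state, "trio", "sim", "bin")
    truth: synthio.TruthSet = state["truth"]
    reads: synthio.ReadSet = state["reads"]
    bcfg = kmerbin.BinningConfig(k=config.k, min_count=1, max_count=10)
    db_a = kmerbin.build_kmer_db(trio.parent_a, config.k)
    db_b = kmerbin.build_kmer_db(trio.parent_b, config.k)
    klu_a = kmerbin.unique_kmers(db_a, db_b, bcfg)
    klu_b = kmerbin.unique_kmers(db_b, db_a, bcfg)
    result = kmerbin.partition_reads(
        [(rid, seq) for rid, seq, _ in reads.long_reads], klu_a, klu_b, bcfg
    )
    (out / "partition_report.tsv").write_text(result.report.to_tsv())
    correct = total = 0
    for rc in result.classifications:
        if rc.label in ("A", "B"):
            total += 1
            correct += truth.read_origin[rc.read_id] == rc.label
    state["partition"] = result
    summary["bin"] = {
        "fractions": result.report.fractions,
        "assignment_accuracy": correct / total if total else None,
    }


def _stage_aln(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    truth: synthio.TruthSet = _require(state, "truth", "sim", "aln")
    blocks = [
        alnmetrics.cigar_block(truth.truth_cigars[lin]) for lin in ("A", "B")
    ]
    decomp = alnmetrics.aggregate_blocks(blocks)
    table = alnmetrics.block_metrics_table(blocks)
    table.to_csv(out / "alignment_metrics.tsv", sep="\t", index=False)
    state["decomposition"] = decomp
    summary["aln"] = {
        "rate_mismatch": decomp.rate_mismatch,
        "rate_small_indel": decomp.rate_small_indel,
        "rate_large_indel": decomp.rate_large_indel,
        "rate_total_uncompressed": decomp.rate_total_uncompressed,
    }


def _stage_ortho(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    from . import orthocomp

    gff = _require(state, "gff", "sim", "ortho")
    genomes = state["genomes"]
    models_a = orthocomp.read_gene_models(gff["A"])
    models_b = orthocomp.read_gene_models(gff["B"])
    pairs = orthocomp.extract_pairs(state["ortho"], models_a, models_b)
    ga = {"chrA1": genomes["A"]}
    gb = {"chrB1": genomes["B"]}
    regions = ["cds", "pep", "int", "up2k", "dn2k"]
    for pair in pairs:
        orthocomp.compare_pair(pair, ga, gb, regions=regions)
    table = orthocomp.pairs_table(pairs)
    table.to_csv(out / "ortholog_pairs.tsv", sep="\t", index=False)
    state["pairs"] = pairs
    summary["ortho"] = {
        "n_pairs": len(pairs),
        "mean_cds_identity": float(table["cds"].mean()),
        "n_highly_conserved": int(table["highly_conserved"].sum()),
    }


def _stage_domains(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    species = [f"sp{i}" for i in range(8)]
    base = rng.integers(5, 40, size=(30, len(species)))
    table = pd.DataFrame(base, columns=species,
                         index=[f"PF{i:05d}" for i in range(30)])
    # plant a few clear expansions
    for row in (0, 1, 2):
        table.iloc[row, row] = int(table.iloc[row].max() * 2 + 10)
    scan = domexp.scan_table(table)
    scan.to_csv(out / "domain_scan.tsv", sep="\t", index=False)
    summary["domains"] = {
        "n_domains": len(scan),
        "n_expanded": int(scan["expanded_in"].notna().sum()),
    }


def _stage_pop(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    vcf_path = out / "population.vcf"
    if not vcf_path.exists():
        raise DependencyError("stage 'pop' needs the sim stage's VCF output")
    gm = popstats.read_vcf(str(vcf_path))
    gm = popstats.filter_snps(gm)
    popmap = pd.read_csv(out / "popmap.tsv", sep="\t", header=None,
                         names=["sample", "population"])
    pops = {
        p: popmap.loc[popmap["population"] == p, "sample"].tolist()
        for p in sorted(popmap["population"].unique())
    }
    cls = popstats.classify_snps(gm, pops)
    pi = popstats.window_pi(gm, pops, window=config.window)
    fst = popstats.window_fst(gm, pops, window=config.window)
    windows = pi.merge(fst, on=["chrom", "start", "end"])
    windows.to_csv(out / "pop_windows.tsv", sep="\t", index=False)
    summary["pop"] = {
        "n_snps": gm.n_sites,
        "n_specific": int((cls.snp_class == "specific").sum()),
        "n_enriched": int((cls.snp_class != "none").sum()),
        "median_fst": float(np.nanmedian(windows["fst"])),
    }


def _stage_stats(config: RunConfig, out: Path, state: dict, summary: dict) -> None:
    genomes = _require(state, "genomes", "sim", "stats")
    stats_a = asmstats.assembly_stats([len(genomes["A"])])
    gene_stats = asmstats.gene_set_stats(state["gff"]["A"], len(genomes["A"]))
    summary["stats"] = {
        "assembly": dataclasses.asdict(stats_a),
        "genes": dataclasses.asdict(gene_stats),
    }


_STAGE_FUNCS = {
    "sim": _stage_sim,
    "bin": _stage_bin,
    "aln": _stage_aln,
    "ortho": _stage_ortho,
    "domains": _stage_domains,
    "pop": _stage_pop,
    "stats": _stage_stats,
}
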