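"""Configuration-driven end-to-end pipeline.

One YAML config drives the whole run: QC -> ROH -> inbreeding -> islands ->
iHS -> LD/Ne, each stage individually skippable, all randomness under one
seed, every table written as TSV next to a run log that echoes the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import filter_variants, read_pedigree, read_plink_text, read_vcf, write_bed, write_pedigree, write_vcf
from .roh import ROHParams, call_roh, summarize_roh
from .inbreeding import inbreeding_correlations, inbreeding_table, summary_stats
from .islands import detect_coldspots, detect_islands, islands_to_frame, snp_roh_incidence
from .ihs import HaplotypeSet, ihs_scan, island_ihs_summary, read_phased_vcf
from .diversity import bin_ld, heterozygosity, ld_r2
from .ne import ne_trajectory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


def _strict_fields(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


@dataclass
class QCConfig:
    maf_min: float = 0.05
    sample_genotyped_min: float = 0.30
    autosomes: list | None = None


@dataclass
class SimulateConfig:
    n_individuals: int = 50
    n_founders: int = 60
    chrom_lengths_mb: list = field(default_factory=lambda: [50.0, 50.0])
    snp_spacing_bp: int = 13_600
    maf_range: list = field(default_factory=lambda: [0.05, 0.5])
    rho: float = 0.9
    planted_fraction: float = 0.15
    planted_mean_length_mb: float = 4.11


@dataclass
class IslandConfig:
    top_fraction: float = 0.005


@dataclass
class IHSConfig:
    maf_min: float = 0.05
    bin_width: float = 0.05
    cm_per_mb: float = 1.0
    ehh_cutoff: float = 0.05


@dataclass
class NeConfig:
    alpha: float = 1.0
    mapping: str = "haldane"
    beta: float = 2.0
    max_dist_bp: float = 10_000_000
    n_bins: int = 50
    min_dist_bp: float = 50_000
    min_pairs: int = 50
    max_pairs_per_snp: int | None = 200


@dataclass
class RunConfig:
    """Full pipeline configuration; serializes to/from one YAML file."""

    genotypes: str | None = None  # .vcf or PLINK prefix (.ped/.map)
    pedigree: str | None = None
    haplotypes: str | None = None  # phased VCF for iHS on real data
    out_dir: str = "rohscan_out"
    seed: int = 1
    stages: list = field(
        default_factory=lambda: ["qc", "roh", "inbreeding", "islands", "ld", "ne"]
    )
    l_auto_bp: int | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    roh: ROHParams = field(default_factory=ROHParams)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    islands: IslandConfig = field(default_factory=IslandConfig)
    ihs: IHSConfig = field(default_factory=IHSConfig)
    ne: NeConfig = field(default_factory=NeConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        _strict_fields(cls, data, "top level")
        sub = {
            "qc": QCConfig,
            "roh": ROHParams,
            "simulate": SimulateConfig,
            "islands": IslandConfig,
            "ihs": IHSConfig,
            "ne": NeConfig,
        }
        kwargs = {}
        for k, v in data.items():
            if k in sub:
                _strict_fields(sub[k], v, k)
                kwargs[k] = sub[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _preflight(cfg: RunConfig) -> None:
    needs_genotypes = {"qc", "roh", "inbreeding", "islands", "ld", "ne"}
    if (
        needs_genotypes & set(cfg.stages)
        and cfg.genotypes is None
        and "simulate" not in cfg.stages
    ):
        raise ValueError("genotype input (or a simulate stage) is required")
    if "ihs" in cfg.stages and cfg.haplotypes is None and "simulate" not in cfg.stages:
        raise ValueError("iHS stage requested but no phased haplotypes available")
    if "inbreeding" in cfg.stages and "roh" not in cfg.stages:
        raise ValueError("inbreeding stage requires the roh stage")
    if "islands" in cfg.stages and "roh" not in cfg.stages:
        raise ValueError("islands stage requires the roh stage")
    if "ne" in cfg.stages and "ld" not in cfg.stages:
        raise ValueError("ne stage requires the ld stage")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns a dict of in-memory results.

    All outputs are TSV/BED/JSON files under ``cfg.out_dir``; the run log
    records the package version, seed and full parameter echo.
    """
    _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("rohscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    results: dict = {}
    try:
        logger.info("rohscan %s seed=%d stages=%s", __version__, cfg.seed, cfg.stages)
        cfg.to_yaml(str(out / "config_echo.yaml"))
        rng = np.random.default_rng(cfg.seed)

        ds = None
        haps = None
        truth = None
        ped = read_pedigree(cfg.pedigree) if cfg.pedigree else None

        if "simulate" in cfg.stages:
            from .simulate import make_map, plant_roh, sample_founders

            sc = cfg.simulate
            vmap, chrom_lengths = make_map(
                {str(i + 1): int(L * 1e6) for i, L in enumerate(sc.chrom_lengths_mb)},
                spacing_bp=sc.snp_spacing_bp,
                seed=int(rng.integers(2**31)),
            )
            pool = sample_founders(
                sc.n_founders,
                vmap,
                maf_range=tuple(sc.maf_range),
                rho=sc.rho,
                seed=int(rng.integers(2**31)),
                chrom_lengths=chrom_lengths,
            )
            haps = pool.to_haplotype_set()
            base = _diploids_from_pool(pool, sc.n_individuals, int(rng.integers(2**31)))
            ds, truth = plant_roh(
                base,
                sc.planted_fraction,
                (sc.planted_mean_length_mb, "exponential"),
                seed=int(rng.integers(2**31)),
            )
            write_vcf(ds, str(out / "simulated.vcf"))
            truth.tracts.to_csv(out / "truth_tracts.tsv", sep="\t", index=False)
            truth.f_true.rename_axis("sample").to_csv(out / "truth_f.tsv", sep="\t")
            results["truth"] = truth
        elif cfg.genotypes:
            ds = (
                read_vcf(cfg.genotypes)
                if cfg.genotypes.endswith(".vcf") or cfg.genotypes.endswith(".vcf.gz")
                else read_plink_text(cfg.genotypes + ".ped", cfg.genotypes + ".map")
            )
        if cfg.haplotypes:
            haps = read_phased_vcf(cfg.haplotypes)

        if ds is not None and cfg.l_auto_bp:
            ds.l_auto_override_bp = cfg.l_auto_bp

        if "qc" in cfg.stages and ds is not None:
            autosomes = set(map(str, cfg.qc.autosomes)) if cfg.qc.autosomes else None
            ds, report = filter_variants(
                ds, cfg.qc.maf_min, cfg.qc.sample_genotyped_min, autosomes
            )
            logger.info("QC kept %d/%d variants", report.n_kept, report.n_input)
            results["qc_report"] = report

        rohset = None
        if "roh" in cfg.stages:
            rohset = call_roh(ds, cfg.roh)
            rohset.to_tsv(str(out / "roh_segments.tsv"))
            summary = summarize_roh(rohset, ds.l_auto_bp, ds.n_samples)
            summary.to_csv(out / "roh_summary.tsv", sep="\t")
            write_bed(rohset.intervals(), str(out / "roh_segments.bed"))
            results["rohset"] = rohset
            results["roh_summary"] = summary
            logger.info("called %d ROH segments", rohset.n_segments)

        if "inbreeding" in cfg.stages:
            table = inbreeding_table(ds, rohset, ped=ped)
            table.to_csv(out / "inbreeding.tsv", sep="\t")
            summary_stats(table).to_csv(out / "inbreeding_summary.tsv", sep="\t")
            inbreeding_correlations(table).to_csv(
                out / "inbreeding_correlations.tsv", sep="\t"
            )
            results["inbreeding"] = table

        track = None
        if "islands" in cfg.stages:
            track = snp_roh_incidence(rohset, ds.variants, ds.n_samples)
            track.to_frame().to_csv(out / "roh_incidence.tsv", sep="\t", index=False)
            try:
                isl, threshold = detect_islands(track, cfg.islands.top_fraction)
            except ValueError as exc:
                logger.warning("island detection skipped: %s", exc)
                isl, threshold = [], float("nan")
            cold = detect_coldspots(track)
            cold.to_csv(out / "roh_coldspots.tsv", sep="\t", index=False)
            results["islands"] = isl
            results["island_threshold"] = threshold
            results["coldspots"] = cold

        if "ihs" in cfg.stages:
            if haps is None:
                raise ValueError("iHS stage requires phased haplotypes")
            ihs_res = ihs_scan(
                haps,
                maf_min=cfg.ihs.maf_min,
                bin_width=cfg.ihs.bin_width,
                cm_per_mb=cfg.ihs.cm_per_mb,
                ehh_cutoff=cfg.ihs.ehh_cutoff,
            )
            ihs_res.to_tsv(str(out / "ihs.tsv"))
            results["ihs"] = ihs_res
            if "islands" in cfg.stages and results.get("islands"):
                isl, r = island_ihs_summary(results["islands"], ihs_res, track)
                results["incidence_ihs_r"] = r

        if "islands" in cfg.stages:
            df = islands_to_frame(results["islands"])
            df.to_csv(out / "roh_islands.tsv", sep="\t", index=False)
            write_bed(
                [r.interval() for r in results["islands"]],
                str(out / "roh_islands.bed"),
            )

        if "ld" in cfg.stages:
            het = heterozygosity(ds)
            with open(out / "heterozygosity.json", "w") as fh:
                json.dump({k: v for k, v in het.items() if np.isscalar(v)}, fh, indent=1)
            pairs = ld_r2(
                ds,
                max_dist_bp=cfg.ne.max_dist_bp,
                max_pairs_per_snp=cfg.ne.max_pairs_per_snp,
                seed=cfg.seed,
            )
            edges = np.geomspace(cfg.ne.min_dist_bp, cfg.ne.max_dist_bp, cfg.ne.n_bins + 1)
            bins = bin_ld(
                pairs,
                ds.n_samples,
                edges_bp=edges,
                beta=cfg.ne.beta,
                mapping=cfg.ne.mapping,
            )
            results["heterozygosity"] = het
            results["ld_bins"] = bins
            import pandas as pd

            pd.DataFrame(
                [dataclasses.asdict(b) for b in bins]
            ).to_csv(out / "ld_decay.tsv", sep="\t", index=False)

        if "ne" in cfg.stages:
            traj = ne_trajectory(results["ld_bins"], alpha=cfg.ne.alpha,
                                 min_pairs=cfg.ne.min_pairs)
            traj.to_tsv(str(out / "ne_trajectory.tsv"))
            results["ne"] = traj

        results["dataset"] = ds
        return results
    finally:
        root.removeHandler(handler)
        handler.close()


def _diploids_from_pool(pool, n_individuals: int, seed: int):
    from .simulate import diploids_from_pool

    return diploids_from_pool(pool, n_individuals, seed)
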