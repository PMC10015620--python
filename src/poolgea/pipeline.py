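"""Stage orchestration with manifests and fixed-seed reproducibility.

Each stage is a plain function over files + in-memory objects; the CLI and
the numbered analysis drivers are thin wrappers around these.  A single
global seed is expanded per stage through a documented sequence
(seed + fixed offset per stage) so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ecology, enrichment, genes as genes_mod, vcfio
from .core import GeaConfig, ScanResult, run_gea
from .localscore import LocalScoreConfig, call_zones
from .simulate import SimulationConfig, write_synthetic_inputs

log = logging.getLogger(__name__)

# per-stage seed offsets (documented expansion of the global seed)
SEED_OFFSETS = {"simulate": 0, "ecology": 101, "scan": 202, "zones": 303, "enrich": 404}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Manifest:
    """Run manifest: config snapshot, input digests, seeds, timings."""

    def __init__(self, outdir: Path, seed: int):
        self.data = {
            "version": __version__,
            "seed": seed,
            "stages": {},
            "inputs": {},
            "outputs": {},
        }
        self.outdir = outdir

    def record(self, stage: str, elapsed: float, **extra) -> None:
        self.data["stages"][stage] = {"elapsed_s": round(elapsed, 3), **extra}

    def add_files(self, kind: str, paths: dict[str, Path]) -> None:
        for name, p in paths.items():
            self.data[kind][name] = {"path": str(p), "sha256": _digest(Path(p))}

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, default=str) + "\n")
        return path


def stage_simulate(
    config: SimulationConfig, outdir: Path, spike_block_size: int = 1
) -> dict[str, Path]:
    return write_synthetic_inputs(outdir, config, spike_block_size=spike_block_size)


def stage_ecology(
    visits_path: Path, env_path: Path, outdir: Path, rho_max: float = 0.8
) -> dict[str, Path]:
    visits = pd.read_csv(visits_path, sep="\t", index_col=0)
    env = pd.read_csv(env_path, sep="\t", index_col=0)
    indices = ecology.network_indices(visits)
    merged = env.join(indices)
    retained = ecology.spearman_prune(merged, rho_max=rho_max)
    pca = ecology.env_pca(merged[retained])
    paths = {
        "indices": outdir / "network_indices.tsv",
        "env_full": outdir / "env_with_indices.tsv",
        "env_pruned": outdir / "env_pruned.tsv",
        "pca_scores": outdir / "env_pca_scores.tsv",
    }
    indices.to_csv(paths["indices"], sep="\t", float_format="%.6g")
    merged.to_csv(paths["env_full"], sep="\t", float_format="%.6g")
    merged[retained].to_csv(paths["env_pruned"], sep="\t", float_format="%.6g")
    pca["scores"].to_csv(paths["pca_scores"], sep="\t", float_format="%.6g")
    return paths


def stage_scan(
    vcf_path: Path,
    env_path: Path,
    outdir: Path,
    gea_config: GeaConfig | None = None,
    scaffold_whitelist: set[str] | None = None,
) -> tuple[ScanResult, dict[str, Path]]:
    counts = vcfio.read_pool_vcf(vcf_path)
    counts, report = vcfio.filter_snps(counts, scaffold_whitelist=scaffold_whitelist)
    freqs = vcfio.allele_frequencies(counts)
    env = pd.read_csv(env_path, sep="\t", index_col=0)
    scan = run_gea(freqs, env, gea_config)
    paths = {
        "scan": outdir / "scan_result.tsv",
        "omega": outdir / "omega.tsv",
        "filter_report": outdir / "filter_report.json",
        "frequencies": outdir / "allele_frequencies.tsv",
    }
    scan.to_tsv(paths["scan"])
    scan.omega.to_tsv(paths["omega"], freqs.pop_labels)
    report.to_json(paths["filter_report"])
    vcfio.write_frequency_tsv(freqs, paths["frequencies"])
    return scan, paths


def stage_zones(
    scan: ScanResult, outdir: Path, ls_config: LocalScoreConfig | None = None
) -> tuple[dict[str, list], dict[str, Path]]:
    ls_config = ls_config or LocalScoreConfig()
    scaffolds = scan.table["scaffold"].to_numpy()
    positions = scan.table["pos"].to_numpy()
    per_variable = {}
    rows = []
    for variable in scan.variables:
        h, thresholds, zones = call_zones(
            scan.bf(variable), scaffolds, positions, ls_config, variable
        )
        per_variable[variable] = zones
        scan.table[f"lindley_{variable}"] = h
        rows.extend(asdict(z) for z in zones)
    zone_df = pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "n_snps", "peak", "peak_pos", "variable"],
    )
    paths = {
        "zones": outdir / "significant_zones.tsv",
        "zones_bed": outdir / "significant_zones.bed",
        "lindley": outdir / "lindley_tracks.tsv",
    }
    zone_df.to_csv(paths["zones"], sep="\t", index=False, float_format="%.6g")
    all_zones = [z for zs in per_variable.values() for z in zs]
    from .localscore import zones_to_bed

    zones_to_bed(all_zones, paths["zones_bed"])
    scan.to_tsv(paths["lindley"])
    return per_variable, paths


def stage_enrich(
    scan: ScanResult,
    outdir: Path,
    ls_config: LocalScoreConfig | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Path]]:
    table = enrichment.enrichment_table(
        scan, ls_config, n_perm=n_perm, seed=seed
    )
    paths = {"enrichment": outdir / "enrichment_table.tsv"}
    table.to_csv(paths["enrichment"], sep="\t", index=False, float_format="%.6g")
    return table, paths


def stage_genes(
    per_variable_zones: dict[str, list],
    gff_path: Path,
    outdir: Path,
) -> dict[str, Path]:
    gene_list = genes_mod.read_gff_genes(gff_path)
    cands = genes_mod.candidate_table(per_variable_zones, gene_list)
    sets = {
        v: set(cands.loc[cands["variable"] == v, "gene_id"])
        for v in cands["variable"].unique()
    }
    paths = {
        "candidates": outdir / "candidate_genes.tsv",
        "sharing": outdir / "gene_sharing.tsv",
    }
    cands.to_csv(paths["candidates"], sep="\t", index=False)
    if sets:
        genes_mod.shared_gene_sets(sets).to_csv(paths["sharing"], sep="\t", index=False)
    else:
        paths["sharing"].write_text("combination\tdegree\texclusive_size\n")
    return paths


def run_all(
    config: SimulationConfig,
    outdir: str | Path,
    seed: int | None = None,
    gea_config: GeaConfig | None = None,
    ls_config: LocalScoreConfig | None = None,
    n_perm: int = 1000,
) -> Manifest:
    """simulate -> filter -> GEA -> local score -> enrichment -> genes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    if seed != config.seed:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    manifest = Manifest(outdir, seed)

    t0 = time.time()
    inputs = stage_simulate(config, outdir / "inputs")
    manifest.record("simulate", time.time() - t0, seed=seed + SEED_OFFSETS["simulate"])
    manifest.add_files("inputs", inputs)

    t0 = time.time()
    eco_paths = stage_ecology(inputs["visits"], inputs["env"], outdir)
    manifest.record("ecology", time.time() - t0)
    manifest.add_files("outputs", eco_paths)

    t0 = time.time()
    gea_config = gea_config or GeaConfig(seed=seed + SEED_OFFSETS["scan"])
    scan, scan_paths = stage_scan(
        inputs["vcf"], eco_paths["env_pruned"], outdir, gea_config
    )
    manifest.record("scan", time.time() - t0, n_snps=len(scan.table))
    manifest.add_files("outputs", scan_paths)

    t0 = time.time()
    ls_config = ls_config or LocalScoreConfig(seed=seed + SEED_OFFSETS["zones"])
    per_variable_zones, zone_paths = stage_zones(scan, outdir, ls_config)
    manifest.record("zones", time.time() - t0)
    manifest.add_files("outputs", zone_paths)

    t0 = time.time()
    _, enr_paths = stage_enrich(
        scan, outdir, ls_config, n_perm=n_perm, seed=seed + SEED_OFFSETS["enrich"]
    )
    manifest.record("enrich", time.time() - t0)
    manifest.add_files("outputs", enr_paths)

    t0 = time.time()
    gene_paths = stage_genes(per_variable_zones, inputs["gff"], outdir)
    manifest.record("genes", time.time() - t0)
    manifest.add_files("outputs", gene_paths)

    manifest.write()
    return manifest
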