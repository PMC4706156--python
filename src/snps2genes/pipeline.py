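"""End-to-end orchestration: QC -> association -> SNP-to-gene mapping ->
gene-based tests -> disease-associated gene selection -> GO enrichment.

A :class:`RunConfig` (buildable from YAML) fixes every stage's thresholds and a
single global seed; each stage draws randomness from a named substream so the
stages are pure functions of (inputs, config, seed). A JSON manifest records
per-stage parameters, timings and output hashes; rerunning an identical config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as genio
from .errors import ConfigError
from .simulate import SimConfig, simulate_cohort
from .qc import run_qc
from .assoc import assoc_scan, bonferroni_threshold, select_suggestive
from .genemap import assign_snps
from .genetests import gene_based_scan, dag_select
from .enrich import decorrelate_run, gene_scores, group_terms

_STAGES = ("input", "qc", "assoc", "snp2gene", "genetests", "dag_select", "enrichment")


@dataclass
class RunConfig:
    out_dir: str = "results"
    seed: int = 0
    # input: either a simulation config or on-disk paths
    sim: SimConfig | None = None
    ped_path: str | None = None
    map_path: str | None = None
    gene_ranges_path: str | None = None
    go_annotation_path: str | None = None
    go_edges_path: str | None = None
    # stage parameters
    n_pcs: int = 4
    maf_min: float = 0.01
    rsq_min: float = 0.80
    outlier_sd: float = 6.0
    pihat_max: float = 0.1875
    flank: int = 5000
    gene_methods: tuple[str, ...] = ("gates", "spca", "skat")
    fdr_cutoff: float = 0.05
    dag_p_assoc: float = 1e-4
    dag_p_fdr: float = 0.1
    enrich_algorithm: str = "weight01"
    enrich_min_genes: int = 8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "gene_methods" in raw:
            raw["gene_methods"] = tuple(raw["gene_methods"])
        return cls(**raw)

    def validate(self) -> None:
        if self.sim is None and (self.ped_path is None or self.map_path is None):
            raise ConfigError("either a simulation config or PED/MAP paths are required")
        for p in (self.ped_path, self.map_path, self.gene_ranges_path,
                  self.go_annotation_path, self.go_edges_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if (self.go_annotation_path is None) != (self.go_edges_path is None):
            raise ConfigError("GO annotation and edge files must be given together")
        if not 0 < self.fdr_cutoff < 1:
            raise ConfigError("fdr_cutoff must be in (0, 1)")


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Named substream: independent randomness per stage under one global seed."""
    digest = hashlib.sha256(stage.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence([seed, key])


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    manifest: dict = {
        "config": json.loads(json.dumps(cfg_dict, default=str)),
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
    }

    def record(stage: str, t0: float, files: dict[str, Path], **extra) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {k: str(v) for k, v in files.items()},
            "hashes": {k: _hash_file(v) for k, v in files.items()},
            **extra,
        }

    try:
        # input
        t0 = time.perf_counter()
        if config.sim is not None:
            sim_seed = int(stage_seed(config.seed, "input").generate_state(1)[0] % (2**31))
            sim_cfg = SimConfig(**{**asdict(config.sim), "seed": sim_seed,
                                   "blocks": config.sim.blocks})
            cohort = simulate_cohort(sim_cfg)
            dosages, variants, samples = cohort.dosages, cohort.variants, cohort.samples
        else:
            dosages, variants, samples = genio.read_ped_map(config.ped_path, config.map_path)
        record("input", t0, {}, n_samples=int(dosages.shape[0]), n_snps=int(dosages.shape[1]))

        # qc
        t0 = time.perf_counter()
        dosages, variants, samples, qc_report = run_qc(
            dosages, variants, samples, n_axes=config.n_pcs,
            maf_min=config.maf_min, rsq_min=config.rsq_min,
            outlier_sd=config.outlier_sd, pihat_max=config.pihat_max,
        )
        files = genio.write_results(
            {"qc_removed_samples": qc_report.removed_samples,
             "qc_removed_snps": qc_report.removed_snps}, out)
        record("qc", t0, files,
               n_samples=int(dosages.shape[0]), n_snps=int(dosages.shape[1]))

        # association
        t0 = time.perf_counter()
        pc_cols = [c for c in samples.columns if c.startswith("PC")][: config.n_pcs]
        covariates = np.column_stack(
            [(samples["sex"] == 2).astype(float).to_numpy()]
            + [samples[c].to_numpy() for c in pc_cols]
        )
        assoc_df = assoc_scan(dosages, samples["status"].to_numpy(), covariates,
                              snp_ids=variants["snp"].tolist())
        threshold = bonferroni_threshold(0.05, len(assoc_df))
        tiers = select_suggestive(assoc_df)
        files = genio.write_results(
            {"assoc": assoc_df, "assoc_tier1": tiers["tier1"], "assoc_tier2": tiers["tier2"]},
            out)
        record("assoc", t0, files, bonferroni_threshold=threshold)

        # snp2gene
        t0 = time.perf_counter()
        if config.gene_ranges_path is not None:
            gene_ranges = genio.read_gene_ranges(config.gene_ranges_path)
        else:
            # one pseudo-gene per simulated LD block (chrom-wide range)
            gene_ranges = pd.DataFrame(
                [{"gene": f"gene_chr{c}", "chrom": c,
                  "start": int(variants.loc[variants["chrom"] == c, "pos"].min()),
                  "end": int(variants.loc[variants["chrom"] == c, "pos"].max())}
                 for c in variants["chrom"].unique()]
            )
        gene_map, coverage = assign_snps(variants, gene_ranges, flank=config.flank)
        map_df = pd.DataFrame(
            [{"gene": g, "n_snps": len(idx),
              "snp_ids": ",".join(variants["snp"].iloc[idx])}
             for g, idx in sorted(gene_map.items())]
        )
        files = genio.write_results({"snp2gene": map_df}, out)
        (out / "snp2gene_coverage.json").write_text(json.dumps(coverage.to_dict(), indent=2))
        files["coverage"] = out / "snp2gene_coverage.json"
        record("snp2gene", t0, files, **coverage.to_dict())

        # gene tests
        t0 = time.perf_counter()
        gene_df = gene_based_scan(
            dosages, samples["status"].to_numpy(), variants, gene_map,
            covariates=covariates, methods=config.gene_methods,
            snp_pvalues=assoc_df["p"].to_numpy(),
        )
        files = genio.write_results({"gene_tests": gene_df}, out)
        n_sig = int((gene_df["p_fdr"] < config.fdr_cutoff).sum())
        record("genetests", t0, files, n_significant=n_sig)

        # disease-associated gene selection
        t0 = time.perf_counter()
        dag_df = dag_select(assoc_df, gene_map, gene_df,
                            p_assoc=config.dag_p_assoc, p_fdr=config.dag_p_fdr)
        files = genio.write_results({"disease_associated_genes": dag_df}, out)
        record("dag_select", t0, files, n_genes=len(dag_df))

        # enrichment (optional)
        if config.go_annotation_path is not None:
            t0 = time.perf_counter()
            go = genio.read_go(config.go_annotation_path, config.go_edges_path)
            scores = gene_scores(gene_df)
            term_df = group_terms(decorrelate_run(
                go, scores, algorithm=config.enrich_algorithm,
                min_genes=config.enrich_min_genes))
            files = genio.write_results({"enrichment_terms": term_df}, out)
            record("enrichment", t0, files,
                   n_terms=len(term_df), n_tested=int(term_df["p"].notna().sum()))
    except Exception as exc:
        failed = next((s for s in _STAGES if s not in manifest["stages"]), "unknown")
        manifest["error"] = {"stage": failed, "message": str(exc)}
        (Path(config.out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
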