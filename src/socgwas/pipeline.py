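"""End-to-end orchestration: phenotypes -> dEBVs -> GRM -> GWAS -> haplotypes.

A run is driven by a configuration dict (or YAML file) and writes every stage
output plus a machine-readable manifest under one directory. All randomness
flows from the configured seed, and tables are written with fixed float
formatting, so two runs from the same manifest are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genio import GenotypeMatrix
from .grm import grm_centered
from .gwas import (MixedModelGWAS, bonferroni_thresholds, format_threshold,
                   genomic_lambda)
from .haplo import alleles_table, blocks_table, gabriel_blocks, hap_gwas
from .qc import qc_markers
from .report import manhattan_table, overlap_hits, qtl_regions_table, significant_hits
from .sim import SimConfig, simulate_cohort
from .social import SocialGeneticModel, build_design
from .traits import derive_trait_table

_FLOAT_FMT = "%.10g"

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},          # SimConfig overrides
    "trait": "ADFI",
    "qc": {"call_rate_min": 0.90, "maf_min": 0.05, "hwe_min": 1e-6},
    "reml": {"estimate_cov_ds": True, "maxiter": 200, "tol": 1e-8},
    "gwas": {"mode": "p3d", "lambda_method": "median"},
    "blocks": {"strong_low_ci": 0.8, "strong_high_ci": 0.98,
               "recomb_high_ci": 0.90, "strong_fraction": 0.95,
               "max_kb": 1000.0, "marker_missing_max": 0.1},
    "hap": {"allele_freq_min": 0.01},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = path_or_dict or {}
    return _merge(DEFAULT_CONFIG, user)


def _write_assoc(path: Path, assoc: pd.DataFrame, thresholds, lam: float) -> None:
    gw, sugg = thresholds
    with open(path, "w") as fh:
        fh.write(f"# socgwas association table\n")
        fh.write(f"# n_tests\t{int(assoc['p'].notna().sum())}\n")
        fh.write(f"# genome_wide\t{gw:.10e}\t(displayed {format_threshold(gw)})\n")
        fh.write(f"# suggestive\t{sugg:.10e}\t(displayed {format_threshold(sugg)})\n")
        fh.write(f"# lambda\t{lam:.6f}\n")
        assoc.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config, outdir: str | Path) -> Path:
    """Run every stage on a seeded simulation; returns the output directory."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": cfg}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log_lines: list[str] = []

    # --- stage: simulate ---------------------------------------------------
    try:
        sim_cfg = SimConfig(**{**cfg["simulate"], "seed": cfg["seed"]})
        geno, cohort, latent, visits, truth = simulate_cohort(sim_cfg)
    except Exception as err:
        raise StageError("simulate", str(err)) from err
    cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
    visits.to_csv(outdir / "visits.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
    log_lines.append(f"simulate: n={sim_cfg.n_individuals} snps={sim_cfg.n_snps} "
                     f"seed={sim_cfg.seed}")

    # --- stage: derive traits ---------------------------------------------
    try:
        traits = derive_trait_table(cohort, visits)
    except Exception as err:
        raise StageError("traits", str(err)) from err
    traits.to_csv(outdir / "traits.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)

    # --- stage: QC + GRM ---------------------------------------------------
    try:
        geno_qc, report = qc_markers(geno, **cfg["qc"])
        G = grm_centered(geno_qc)
    except Exception as err:
        raise StageError("qc", str(err)) from err
    with open(outdir / "qc_report.tsv", "w") as fh:
        fh.write("\n".join(report.to_lines()) + "\n")
    log_lines.append(f"qc: retained {report.n_retained}/{report.n_input}")

    # --- stage: social REML + deregression ----------------------------------
    trait_name = cfg["trait"]
    try:
        design = build_design(cohort, trait_name, traits=traits)
        keep = [i for i, s in enumerate(cohort["id"]) if s in set(design.ids)]
        K = G[np.ix_(keep, keep)] if len(keep) != G.shape[0] else G
        reml_cfg = dict(cfg["reml"])
        fit_kwargs = {k: reml_cfg.pop(k) for k in ("maxiter", "tol")
                      if k in reml_cfg}
        model = SocialGeneticModel(design, K, **reml_cfg)
        fit = model.fit(**fit_kwargs)
    except Exception as err:
        raise StageError("reml", str(err)) from err
    (outdir / "reml_summary.txt").write_text(fit.summary() + "\n")
    debv = fit.deregressed_table(trait=trait_name)
    debv.to_csv(outdir / "debv.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
    log_lines.append(
        f"reml: converged={fit.converged} iter={fit.n_iter} "
        f"varcomps={ {k: round(v, 6) for k, v in fit.varcomps.items()} }"
    )

    # --- stage: single-locus GWAS (DGE and SGE responses) -------------------
    id_pos = {s: i for i, s in enumerate(geno.samples)}
    assoc_paths = {}
    hits = {}
    nulls = {}
    try:
        for eff in ("DGE", "SGE"):
            sub = debv.loc[(debv["effect"] == eff) & debv["usable"]]
            rows = [id_pos[s] for s in sub["id"]]
            y = sub["debv"].to_numpy()
            Gy = G[np.ix_(rows, rows)]
            M = geno_qc.dosage[rows]
            gmod = MixedModelGWAS(y, Gy)
            null = gmod.fit_null()
            nulls[eff] = (null, rows)
            assoc = gmod.scan(M, mode=cfg["gwas"]["mode"],
                              markers=geno_qc.markers)
            thr = bonferroni_thresholds(int(assoc["p"].notna().sum()))
            lam = genomic_lambda(assoc["p"].dropna().to_numpy(),
                                 method=cfg["gwas"]["lambda_method"])
            path = outdir / f"assoc_{eff.lower()}.tsv"
            _write_assoc(path, assoc, thr, lam)
            assoc_paths[eff] = path
            hits[eff] = significant_hits(assoc, thr)
            hits[eff].to_csv(outdir / f"hits_{eff.lower()}.tsv", sep="\t",
                             index=False, float_format=_FLOAT_FMT)
            qtl_regions_table(hits[eff]).to_csv(
                outdir / f"qtl_regions_{eff.lower()}.tsv", sep="\t", index=False)
            manhattan_table(assoc).to_csv(
                outdir / f"manhattan_{eff.lower()}.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT)
            log_lines.append(f"gwas {eff}: lambda={lam:.4f} "
                             f"suggestive hits={len(hits[eff])}")
    except Exception as err:
        raise StageError("gwas", str(err)) from err

    # --- stage: overlap -----------------------------------------------------
    parts = overlap_hits(hits["DGE"], hits["SGE"])
    for name, df in parts.items():
        df.to_csv(outdir / f"overlap_{name}.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)

    # --- stage: haplotype blocks + haplotype GWAS ---------------------------
    try:
        blocks = gabriel_blocks(geno_qc, **cfg["blocks"])
        blocks_table(blocks).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        alleles_table(blocks).to_csv(outdir / "hap_alleles.tsv", sep="\t",
                                     index=False, float_format=_FLOAT_FMT)
        for eff in ("DGE", "SGE"):
            null, rows = nulls[eff]
            sub_geno = GenotypeMatrix(
                dosage=geno_qc.dosage[rows],
                phase=None if geno_qc.phase is None else geno_qc.phase[:, rows, :],
                markers=geno_qc.markers,
                samples=[geno_qc.samples[i] for i in rows],
            )
            hassoc = hap_gwas(sub_geno, blocks, null,
                              allele_freq_min=cfg["hap"]["allele_freq_min"],
                              mode=cfg["gwas"]["mode"])
            n_tests = int(hassoc["p"].notna().sum()) if len(hassoc) else 0
            if n_tests:
                thr = bonferroni_thresholds(n_tests)
                lam = genomic_lambda(hassoc["p"].dropna().to_numpy(),
                                     method=cfg["gwas"]["lambda_method"])
            else:
                thr, lam = (np.nan, np.nan), np.nan
            _write_assoc(outdir / f"hap_assoc_{eff.lower()}.tsv", hassoc,
                         thr, lam if np.isfinite(lam) else 0.0)
            log_lines.append(f"hap gwas {eff}: blocks={len(blocks)} "
                             f"alleles={n_tests}")
    except Exception as err:
        raise StageError("haplotypes", str(err)) from err

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def rerun_from_manifest(manifest_path: str | Path, outdir: str | Path) -> Path:
    """Reproduce a run from its manifest; deterministic stage outputs match."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_pipeline(manifest["config"], outdir)
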