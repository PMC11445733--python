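"""End-to-end pipeline: simulate -> qc -> prune -> impute -> evaluate -> popgen.

Driven by a single YAML (or dict) configuration with per-stage sections;
every stage writes its reports into the artifacts directory and the run
ends with a machine-readable manifest listing every output file with a
content hash, so identical configurations produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import run_cv_experiment
from .imputer import build_haplotype_library, impute
from .io import write_bundle
from .panels import PanelDefinition, coverage_report, prune_ladder, thin_panel
from .popgen import (admixture_em, classical_mds, evanno_delta_k, ibs_matrix,
                     individual_heterozygosity, maf_spectrum)
from .qc import QcThresholds, apply_qc
from .simdata import SCENARIOS, SimConfig, simulate_study

DEFAULT_CONFIG = {
    "out_dir": "artifacts",
    "sim": {"scenario": "breeding_population", "seed": 1,
            "n_chromosomes": 27, "markers_per_chromosome": 200},
    "qc": {"maf_min": 0.01, "marker_call_rate_min": 0.9, "hwe_alpha": 0.05,
           "hwe_bonferroni": True, "order": ["hwe", "call_rate", "maf"]},
    "prune": {"r2_thresholds": [0.9, 0.8, 0.7, 0.6], "window": 50, "step": 5,
              "thin_lowest": True},
    "evaluate": {"n_replicates": 10, "validation_fraction": 0.1,
                 "min_window": 32, "n_end": 100, "accuracy_on": "dosage"},
    "popgen": {"k_values": [1, 2, 3], "n_seeds": 5, "mds_dims": 2,
               "panel_markers_only": True},
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    """Fill defaults and check every threshold before any stage runs."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    sim = cfg["sim"]
    if sim["scenario"] not in SCENARIOS:
        raise ConfigError(f"unknown scenario {sim['scenario']!r}")
    qc = cfg["qc"]
    if qc.get("maf_min") is not None and not (0.0 <= qc["maf_min"] <= 0.5):
        raise ConfigError(f"maf_min={qc['maf_min']}: MAF cannot exceed 0.5")
    for key in ("marker_call_rate_min", "hwe_alpha"):
        v = qc.get(key)
        if v is not None and not (0.0 <= v <= 1.0):
            raise ConfigError(f"{key}={v} outside [0, 1]")
    ev = cfg["evaluate"]
    if not (0.0 < ev["validation_fraction"] <= 1.0):
        raise ConfigError("validation_fraction must lie in (0, 1]")
    if ev["n_replicates"] < 1:
        raise ConfigError("n_replicates must be >= 1")
    for thr in cfg["prune"]["r2_thresholds"]:
        if not (0.0 < thr <= 1.0):
            raise ConfigError(f"r2 threshold {thr} outside (0, 1]")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: "dict | str | Path") -> Path:
    """Run every stage; returns the artifacts directory.

    ``config`` is a dict or a path to a YAML file; missing keys fall back
    to :data:`DEFAULT_CONFIG`.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = validate_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    # --- simulate ---------------------------------------------------------
    sim_cfg = SimConfig(**{k: tuple(v) if k == "founder_maf_dist" else v
                           for k, v in cfg["sim"].items() if k != "scenario"})
    study = simulate_study(sim_cfg, cfg["sim"]["scenario"])
    paths = write_bundle(study.bundle, out, prefix="simulated")
    outputs += [Path(p) for p in paths.values()]

    # --- qc ---------------------------------------------------------------
    qc_cfg = {k: v for k, v in cfg["qc"].items() if k != "order"}
    thresholds = QcThresholds(**qc_cfg)
    g_qc, report = apply_qc(study.bundle.genotypes, study.bundle.pedigree,
                            thresholds, cfg["qc"]["order"])
    qc_path = out / "qc_report.tsv"
    report.to_frame().to_csv(qc_path, sep="\t", index=False)
    _write_json(report.steps, out / "qc_report.json")
    outputs += [qc_path, out / "qc_report.json"]
    mmap_qc = study.bundle.marker_map.subset(g_qc.markers)

    # --- prune ------------------------------------------------------------
    pr = cfg["prune"]
    panels = prune_ladder(g_qc, mmap_qc, pr["r2_thresholds"], pr["window"], pr["step"])
    if pr.get("thin_lowest"):
        panels.append(thin_panel(panels[-1], mmap_qc))
    panel_meta = []
    for p in panels:
        p_path = out / f"panel_{p.label}.txt"
        p.write(p_path)
        outputs.append(p_path)
        cov = coverage_report(p, mmap_qc)
        cov_path = out / f"panel_{p.label}_coverage.tsv"
        cov.to_csv(cov_path, sep="\t", index=False)
        outputs.append(cov_path)
        panel_meta.append({"label": p.label, "r2_threshold": p.r2_threshold,
                           "n_markers": len(p), "provenance": p.provenance})
    _write_json(panel_meta, out / "panels.json")
    outputs.append(out / "panels.json")

    # --- impute (demonstration pass on the densest panel) -----------------
    ev = cfg["evaluate"]
    demo_val = list(g_qc.individuals[: max(2, g_qc.n_individuals // 10)])
    demo_ref = [i for i in g_qc.individuals if i not in set(demo_val)]
    g_ref = g_qc.subset(demo_ref)
    lib = build_haplotype_library(g_ref, study.bundle.pedigree, mmap_qc)
    res = impute(g_qc.subset(demo_val, panels[0].markers), g_ref,
                 study.bundle.pedigree, mmap_qc, lib, min_window=ev["min_window"])
    _write_json({"provenance_counts": res.provenance_counts(),
                 "panel": panels[0].label, "n_targets": len(demo_val)},
                out / "impute_demo.json")
    outputs.append(out / "impute_demo.json")

    # --- evaluate ---------------------------------------------------------
    reports, comparison = run_cv_experiment(
        g_qc, study.bundle.pedigree, mmap_qc, panels,
        n_replicates=ev["n_replicates"], validation_fraction=ev["validation_fraction"],
        seed=sim_cfg.seed, min_window=ev["min_window"], accuracy_on=ev["accuracy_on"],
        n_end=ev["n_end"])
    cmp_path = out / "accuracy_comparison.tsv"
    comparison.to_csv(cmp_path, sep="\t", index=False)
    outputs.append(cmp_path)
    for label, rep in reports.items():
        p1 = out / f"accuracy_{label}_per_snp.tsv"
        rep.per_snp.rename_axis("marker").to_csv(p1, sep="\t")
        p2 = out / f"accuracy_{label}_per_individual.tsv"
        rep.per_individual.rename_axis("individual").to_csv(p2, sep="\t")
        outputs += [p1, p2]
    _write_json({label: {"snp": rep.summary_snp, "individual": rep.summary_individual}
                 for label, rep in reports.items()}, out / "accuracy_summary.json")
    outputs.append(out / "accuracy_summary.json")

    # --- popgen -----------------------------------------------------------
    pg = cfg["popgen"]
    g_pop = g_qc.subset(markers=panels[-1].markers) if pg.get("panel_markers_only") else g_qc
    spec_path = out / "maf_spectrum.tsv"
    maf_spectrum(g_pop).to_csv(spec_path, sep="\t", index=False)
    het_path = out / "heterozygosity.tsv"
    individual_heterozygosity(g_pop).rename_axis("individual").to_csv(het_path, sep="\t")
    ibs = ibs_matrix(g_pop)
    coords = classical_mds(ibs.distance, k=pg["mds_dims"])
    mds_path = out / "mds_coordinates.tsv"
    pd.DataFrame(coords, index=ibs.individuals,
                 columns=[f"axis{i + 1}" for i in range(coords.shape[1])]
                 ).rename_axis("individual").to_csv(mds_path, sep="\t")
    ll = {}
    for K in pg["k_values"]:
        ll[K] = [admixture_em(g_pop, K, seed=sim_cfg.seed * 1000 + K * 10 + s
                              ).log_likelihood
                 for s in range(pg["n_seeds"])]
    ll_tab = pd.DataFrame(ll)
    ll_path = out / "admixture_loglik.tsv"
    ll_tab.to_csv(ll_path, sep="\t", index=False)
    outputs += [spec_path, het_path, mds_path, ll_path]
    if len(pg["k_values"]) >= 3:
        dk = evanno_delta_k(ll_tab)
        dk_path = out / "evanno_delta_k.tsv"
        dk.to_csv(dk_path, sep="\t", index=False)
        _write_json({"optimal_k": dk.attrs["optimal_k"]}, out / "evanno_optimum.json")
        outputs += [dk_path, out / "evanno_optimum.json"]

    # --- manifest ---------------------------------------------------------
    manifest = {
        "version": __version__,
        "config": cfg,
        "seed": sim_cfg.seed,
        "files": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    _write_json(manifest, out / "manifest.json")
    return out
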