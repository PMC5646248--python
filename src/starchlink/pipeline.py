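"""End-to-end orchestration of the two headline analyses.

``run_pipeline`` drives the stages — data loading (or synthetic cohort
generation), per-layer preprocessing, dose-correlation mapping, joint
OPLS-DA, and CLR network assembly — from a single configuration mapping,
writing each stage's outputs under a stage-named subdirectory plus a
manifest of seeds, thresholds and output checksums.  Re-running the same
configuration reproduces identical outputs; stages whose inputs are
unchanged (by checksum) are skipped.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .dose_response import dose_correlation
from .metabolomics import align_peaks, filter_snr, read_peaklist
from .microbiome import (
    filter_otus_by_prevalence,
    filter_samples_by_depth,
    relative_abundance,
    scale_to_even_depth,
)
from .network import (
    build_network,
    color_nodes,
    extract_modules,
    hub_report,
    write_edges_tsv,
    write_graphml,
    write_modules_tsv,
    write_nodes_tsv,
)
from .opls import ClassDesign, fit_opls_da, model_summary
from .proteomics import normalize_spectral_counts
from .synthetic import CohortDesign, PlantedEffect, generate_cohort, write_cohort
from .tables import (
    FeatureTable,
    TableError,
    read_feature_table,
    read_sample_meta,
    write_feature_table,
    write_json,
)

log = logging.getLogger("starchlink")

DEFAULT_STAGES = ("data", "microbiome", "proteomics", "dose_response", "opls", "network")


class ConfigError(ValueError):
    """Raised for malformed pipeline configurations."""


def load_config(path: str | Path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    return config


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())
    filehandler = logging.FileHandler(outdir / "pipeline.log")
    filehandler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(filehandler)


def _joint_matrix(tables: Mapping[str, FeatureTable]) -> pd.DataFrame:
    """Concatenate the layers on their shared samples, columns layer:fid."""
    layers = sorted(tables)
    shared = set(tables[layers[0]].sample_ids)
    for layer in layers[1:]:
        shared &= set(tables[layer].sample_ids)
    shared_ids = sorted(shared)
    blocks = []
    for layer in layers:
        frame = tables[layer].data.loc[shared_ids]
        frame = frame.rename(columns=lambda f: f"{layer}:{f}")
        blocks.append(frame.fillna(0.0))
    return pd.concat(blocks, axis=1)


def run_pipeline(config: dict | str | Path) -> Path:
    """Run the configured stages; returns the artifact directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    if "output_dir" not in config:
        raise ConfigError("config needs an output_dir")
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))

    manifest_path = outdir / "manifest.json"
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "output_dir"},
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            name: {"path": str(p.relative_to(outdir)), "sha256": _checksum(p)}
            for name, p in outputs.items()
        }

    # ------------------------------------------------------------------ data
    tables: dict[str, FeatureTable] = {}
    datadir = outdir / "data"
    datadir.mkdir(exist_ok=True)
    if "synthetic" in config:
        params = dict(config["synthetic"])
        effects = [PlantedEffect(**e) for e in params.pop("effects", [])]
        design = CohortDesign(seed=seed, **params)
        tables, meta, truth = generate_cohort(design, effects)
        write_cohort(datadir, tables, meta, truth)
        log.info("generated synthetic cohort: %d subjects", design.n_subjects)
    elif "inputs" in config:
        inputs = config["inputs"]
        if "meta" not in inputs:
            raise ConfigError("inputs must name a meta table")
        meta = read_sample_meta(inputs["meta"])
        for layer in ("otu", "protein", "metabolite"):
            if layer in inputs:
                tables[layer] = read_feature_table(inputs[layer], layer)
                write_feature_table(tables[layer], datadir / f"{layer}_table.tsv")
        meta.to_csv(datadir / "sample_meta.tsv", sep="\t", index=False)
    else:
        raise ConfigError("config needs a synthetic: or inputs: block")
    record("data", {p.name: p for p in sorted(datadir.iterdir())})
    manifest.setdefault("inputs", {})["data"] = {"seed": seed}

    data_sums = {n: r["sha256"] for n, r in manifest["stages"]["data"].items()}
    processed: dict[str, FeatureTable] = {}

    # ------------------------------------------------------------ microbiome
    if "microbiome" in stages and "otu" in tables:
        params = dict(config.get("microbiome", {}))
        min_reads = int(params.get("min_reads", 5000))
        min_count = int(params.get("min_count", 5))
        min_samples = int(params.get("min_samples", 5))
        depth = int(params.get("depth", 5000))
        stagedir = outdir / "microbiome"
        stagedir.mkdir(exist_ok=True)
        table = filter_samples_by_depth(tables["otu"], min_reads)
        table, report = filter_otus_by_prevalence(table, min_count, min_samples)
        scaled = scale_to_even_depth(table, depth)
        processed["otu"] = scaled
        write_feature_table(scaled, stagedir / "otu_scaled.tsv")
        write_json(report.to_jsonable(), stagedir / "filter_report.json")
        record("microbiome", {"otu_scaled.tsv": stagedir / "otu_scaled.tsv",
                              "filter_report.json": stagedir / "filter_report.json"})
        manifest["inputs"]["microbiome"] = data_sums
        log.info("microbiome: %d → %d OTUs (%.1f%% of observations)",
                 report.features_before, report.features_after,
                 100 * report.observation_fraction)
    elif "otu" in tables:
        processed["otu"] = tables["otu"]

    # ------------------------------------------------------------ proteomics
    if "proteomics" in stages and "protein" in tables:
        stagedir = outdir / "proteomics"
        stagedir.mkdir(exist_ok=True)
        normalized = normalize_spectral_counts(tables["protein"])
        processed["protein"] = normalized
        write_feature_table(normalized, stagedir / "protein_normalized.tsv")
        record("proteomics",
               {"protein_normalized.tsv": stagedir / "protein_normalized.tsv"})
        manifest["inputs"]["proteomics"] = data_sums
    elif "protein" in tables:
        processed["protein"] = tables["protein"]

    # ----------------------------------------------------------- metabolomics
    if "metabolite" in tables:
        processed["metabolite"] = tables["metabolite"]
    elif "peaklists" in config.get("metabolomics", {}):
        params = config["metabolomics"]
        peaklists = [read_peaklist(p) for p in params["peaklists"]]
        if params.get("min_snr"):
            peaklists = [filter_snr(pl, float(params["min_snr"])) for pl in peaklists]
        aligned = align_peaks(peaklists, float(params.get("ppm_tol", 1.0)))
        processed["metabolite"] = aligned
        stagedir = outdir / "metabolomics"
        stagedir.mkdir(exist_ok=True)
        write_feature_table(aligned, stagedir / "aligned_matrix.tsv")
        record("metabolomics", {"aligned_matrix.tsv": stagedir / "aligned_matrix.tsv"})

    missing_layers = [l for l in ("otu", "protein", "metabolite") if l not in processed]
    if missing_layers:
        log.warning("layers absent from this run: %s", ", ".join(missing_layers))

    # --------------------------------------------------------- dose response
    if "dose_response" in stages:
        stagedir = outdir / "dose_response"
        stagedir.mkdir(exist_ok=True)
        outputs = {}
        for layer, table in sorted(processed.items()):
            base = relative_abundance(table) if layer == "otu" else table
            result = dose_correlation(base, meta)
            frame = pd.DataFrame(
                {"mean_r": result.mean_r, "n_subjects_used": result.n_subjects_used}
            )
            path = stagedir / f"{layer}_dose_correlation.tsv"
            frame.to_csv(path, sep="\t", index_label="feature_id")
            outputs[path.name] = path
        record("dose_response", outputs)

    # ------------------------------------------------------------------ opls
    if "opls" in stages:
        params = dict(config.get("opls", {}))
        contrast = tuple(params.get("contrast", ("baseline", "HRS")))
        folds = int(params.get("folds", 7))
        orthogonal = params.get("orthogonal", "auto")
        if orthogonal != "auto":
            orthogonal = int(orthogonal)
        stagedir = outdir / "opls"
        stagedir.mkdir(exist_ok=True)
        joint = _joint_matrix(processed)
        design = ClassDesign.from_meta(meta, contrast)
        model = fit_opls_da(joint, design, n_orthogonal=orthogonal, folds=folds)
        write_json(model_summary(model), stagedir / "model_summary.json")
        scores = pd.DataFrame({"t1": model.scores}, index=model.sample_ids)
        for i in range(model.n_orthogonal):
            scores[f"t0_{i + 1}"] = model.ortho_scores[:, i]
        scores.to_csv(stagedir / "scores.tsv", sep="\t", index_label="sample_id")
        loadings = pd.DataFrame({"p1": model.loadings}, index=model.feature_ids)
        loadings.to_csv(stagedir / "loadings.tsv", sep="\t", index_label="feature")
        record("opls", {p.name: p for p in sorted(stagedir.iterdir())})
        log.info("OPLS-DA %s: R2Y=%.3f Q2=%.3f p=%.3g", design.name,
                 model.r2y_cum, model.q2_cum, model.cv_anova_p)

    # --------------------------------------------------------------- network
    if "network" in stages:
        if len(processed) < 2:
            log.warning("network stage skipped: fewer than 2 layers available")
        else:
            params = dict(config.get("network", {}))
            z_threshold = float(params.get("z_threshold", 6.5))
            method = params.get("modules", "components")
            stagedir = outdir / "network"
            stagedir.mkdir(exist_ok=True)
            graph = build_network(processed, meta, z_threshold=z_threshold)
            color_nodes(graph, processed, meta,
                        contrast=tuple(params.get("contrast", ("baseline", "HRS"))))
            modules = extract_modules(graph, method=method, seed=seed)
            write_edges_tsv(graph, stagedir / "edges.tsv")
            write_nodes_tsv(graph, stagedir / "nodes.tsv")
            write_modules_tsv(modules, stagedir / "modules.tsv")
            write_graphml(graph, stagedir / "network.graphml")
            if graph.number_of_nodes():
                hub_report(graph).to_csv(stagedir / "hubs.tsv", sep="\t", index=False)
            record("network", {p.name: p for p in sorted(stagedir.iterdir())})
            log.info("network: %d nodes, %d edges, %d modules",
                     graph.number_of_nodes(), graph.number_of_edges(), len(modules))

    write_json(manifest, manifest_path)
    return outdir
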