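"""End-to-end pipeline orchestration from a YAML config.

Stage order mirrors the analysis workflow: preprocessing ->
differential modeling -> z-score enrichment, with independent motif and
respirometry stages.  Inputs come either from files or from the
synthetic generators (a ``simulate`` block), every stage's output is
written as TSV under the configured output directory, and a JSON
manifest records the seed, parameters and produced files so reruns are
reproducible and auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import OmicsMatrix
from .datasets import ampk_candidate_windows
from .differential import run_differential
from .enrichment import SetCollection, collapse_features, enrich, t_to_z
from .motif import PhosphoWindow, read_windows_tsv, scan_sites, write_summary_tsv
from .bioenergetics import RespirometryAssay, compute_conductance
from .preprocessing import preprocess_matrix
from .synthetic import (
    SimConfig,
    simulate_omics_experiment,
    simulate_set_collection,
)


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration with defaults filled in."""

    output_dir: Path
    seed: int = 0
    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    motif: dict = field(default_factory=dict)
    respirometry: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "output_dir" not in raw:
            raise ValueError("config must set output_dir")
        if raw.get("simulate") is None and not raw.get("inputs"):
            raise ValueError("config needs either a simulate block or inputs")
        return cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs", {}) or {},
            differential=raw.get("differential", {}) or {},
            enrichment=raw.get("enrichment", {}) or {},
            motif=raw.get("motif", {}) or {},
            respirometry=raw.get("respirometry"),
        )


def _load_matrices(config: PipelineConfig) -> tuple[dict[str, OmicsMatrix], pd.DataFrame | None]:
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        effects = {
            (str(f), str(g), str(t)): float(v)
            for f, g, t, v in sim_kwargs.pop("effects", [])
        }
        sim_config = SimConfig(seed=config.seed, effect_table=effects, **sim_kwargs)
        experiment = simulate_omics_experiment(sim_config)
        return experiment.matrices, experiment.truth
    matrices = {}
    for sex, paths in config.inputs.get("matrices", {}).items():
        matrices[sex] = OmicsMatrix.from_tsv(paths["values"], paths.get("samples"))
    return matrices, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary.

    A stage failure raises with the failing stage named; outputs written
    before the failure are left in place.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "muscleomics",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "simulate": config.simulate,
            "differential": config.differential,
            "enrichment": {
                k: config.enrichment.get(k, d)
                for k, d in (
                    ("min_overlap", 10),
                    ("jaccard_cutoff", 0.85),
                    ("rho", 0.01),
                )
            },
        },
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, path: Path) -> None:
        manifest["outputs"].append({"stage": stage, "path": str(path)})

    # -- preprocessing + differential per sex -----------------------------
    stage = "preprocess"
    try:
        matrices, truth = _load_matrices(config)
        if truth is not None:
            truth_path = out / "truth.tsv"
            truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")
            record("simulate", truth_path)
        processed: dict[str, OmicsMatrix] = {}
        for sex, matrix in matrices.items():
            processed[sex] = preprocess_matrix(matrix)
            vpath = out / f"normalized_{sex}.tsv"
            processed[sex].to_tsv(vpath, out / f"samples_{sex}.tsv")
            record(stage, vpath)
        manifest["stages"]["preprocess"] = {
            "sexes": sorted(processed),
            "n_features": {s: m.n_features for s, m in processed.items()},
        }

        stage = "differential"
        diff_tables: dict[str, pd.DataFrame] = {}
        diff_kwargs = {
            "use_sample_weights": bool(config.differential.get("use_sample_weights", False)),
            "trend": bool(config.differential.get("trend", False)),
            "robust": bool(config.differential.get("robust", True)),
        }
        for sex, matrix in processed.items():
            table = run_differential(matrix, **diff_kwargs)
            diff_tables[sex] = table
            dpath = out / f"differential_{sex}.tsv"
            table.to_csv(dpath, sep="\t", index=False, float_format="%.10g")
            record(stage, dpath)
        manifest["stages"]["differential"] = {
            "contrasts": sorted(next(iter(diff_tables.values()))["contrast"].unique())
            if diff_tables
            else [],
            **diff_kwargs,
        }

        stage = "enrichment"
        enr_params = manifest["parameters"]["enrichment"]
        collection = None
        if config.enrichment.get("gmt"):
            collection = SetCollection.from_gmt(config.enrichment["gmt"])
        elif config.simulate is not None and diff_tables:
            # synthesize a redundant collection over the simulated features
            any_table = next(iter(diff_tables.values()))
            universe = sorted(any_table["feature"].unique())
            collection, _ = simulate_set_collection(
                n_true_sets=int(config.enrichment.get("n_true_sets", 10)),
                duplicates_per_set=int(config.enrichment.get("duplicates_per_set", 2)),
                jitter=int(config.enrichment.get("jitter", 1)),
                universe=universe,
                seed=config.seed,
            )
        if collection is not None:
            for sex, table in diff_tables.items():
                ztable = table[["feature", "contrast"]].copy()
                ztable["z"] = t_to_z(table["t"].to_numpy(), table["df"].to_numpy())
                stat_matrix = collapse_features(ztable, {})
                zpath = out / f"zscores_{sex}.tsv"
                stat_matrix.to_csv(zpath, sep="\t", float_format="%.10g")
                record(stage, zpath)
                result = enrich(
                    stat_matrix.dropna(),
                    collection,
                    min_overlap=int(enr_params["min_overlap"]),
                    jaccard_cutoff=float(enr_params["jaccard_cutoff"]),
                    rho=float(enr_params["rho"]),
                )
                epath = out / f"enrichment_{sex}.tsv"
                result.to_csv(epath, sep="\t", index=False, float_format="%.10g")
                record(stage, epath)
            manifest["stages"]["enrichment"] = {"n_sets": len(collection), **enr_params}

        stage = "motif"
        if config.motif.get("windows"):
            windows = read_windows_tsv(config.motif["windows"])
        else:
            panel = ampk_candidate_windows()
            windows = [
                PhosphoWindow(site_id=r.site_id, sequence=r.sequence)
                for r in panel.itertuples()
            ]
        summary = scan_sites(windows)
        mpath = out / "motif_calls.tsv"
        write_summary_tsv(summary, mpath)
        record(stage, mpath)
        manifest["stages"]["motif"] = {
            "n_windows": summary.n_windows,
            "n_strict": summary.n_strict,
            "n_relaxed": summary.n_relaxed,
            "n_minimal": summary.n_minimal,
        }

        stage = "respirometry"
        if config.respirometry is not None:
            assay = RespirometryAssay.from_tsv(config.respirometry["table"])
            result = compute_conductance(
                assay, include_max=bool(config.respirometry.get("include_max", False))
            )
            rpath = out / "conductance.tsv"
            pd.DataFrame(
                [
                    {
                        "slope": result.slope,
                        "intercept": result.intercept,
                        "r_squared": result.r_squared,
                        "n_points": result.n_points,
                        "conductance": result.conductance,
                    }
                ]
            ).to_csv(rpath, sep="\t", index=False, float_format="%.10g")
            record(stage, rpath)
            manifest["stages"]["respirometry"] = {
                "slope": result.slope,
                "conductance": result.conductance,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
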