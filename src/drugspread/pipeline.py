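"""Pipeline orchestration: config validation, stage chaining, manifests.

A YAML config selects stages (simulate, accumulate, taxonomy, network) and
their parameters.  Every run writes a manifest of output files with
content hashes; identical config + seed gives byte-identical outputs.  The
single global seed fans out to per-stage seeds through a stage-name hash,
so adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import accumulation, events_io, propagation, synthetic_data, taxonomy
from .events_io import DEFAULT_WINDOW, ObservationWindow

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "load_config", "run_pipeline", "stage_seed"]

_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "paths": {"output_dir": str, "study_table": str, "adoption_table": str},
    "window": {"t_start": (int, float), "t_max": (int, float)},
    "simulation": {
        "n_diseases": int,
        "edge_density": (int, float),
        "lambda_low": (int, float),
        "lambda_high": (int, float),
        "drugs_per_year": (int, float),
        "year_start": (int, float),
        "year_end": (int, float),
        "alpha_low": (int, float),
        "alpha_high": (int, float),
        "beta_low": (int, float),
        "beta_high": (int, float),
    },
    "accumulation": {"aggregator": str, "min_age": int},
    "taxonomy": {"min_drugs": int},
    "propagation": {"model": str, "t_cut": (int, float)},
}
_TOP_LEVEL = {"stages": list, "rng_seed": int, "log_level": str, **{k: dict for k in _SCHEMA}}
_KNOWN_STAGES = ("simulate", "accumulate", "taxonomy", "network")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    output_dir: Path
    rng_seed: int = 0
    window: ObservationWindow = field(default_factory=lambda: DEFAULT_WINDOW)
    study_table: Path | None = None
    adoption_table: Path | None = None
    simulation: dict[str, Any] = field(default_factory=dict)
    accumulation: dict[str, Any] = field(default_factory=dict)
    taxonomy: dict[str, Any] = field(default_factory=dict)
    propagation: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"


def validate_config(path: str | Path) -> list[str]:
    """Schema-check a config file without executing anything.

    Returns a list of problems; an empty list means the config is valid.
    """
    problems: list[str] = []
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        return [f"malformed YAML: {exc}"]
    if not isinstance(raw, dict):
        return ["config root must be a mapping"]
    for key, value in raw.items():
        if key not in _TOP_LEVEL:
            problems.append(f"unknown key: {key}")
            continue
        if not isinstance(value, _TOP_LEVEL[key]):
            problems.append(f"{key}: expected {_TOP_LEVEL[key]}, got {type(value).__name__}")
            continue
        if key in _SCHEMA:
            for sub, sub_val in value.items():
                if sub not in _SCHEMA[key]:
                    problems.append(f"unknown key: {key}.{sub}")
                elif not isinstance(sub_val, _SCHEMA[key][sub]) or isinstance(sub_val, bool):
                    problems.append(f"{key}.{sub}: wrong type ({type(sub_val).__name__})")
    stages = raw.get("stages", [])
    for s in stages:
        if s not in _KNOWN_STAGES:
            problems.append(f"unknown stage: {s}")
    if "stages" not in raw:
        problems.append("missing required key: stages")
    if "paths" not in raw or "output_dir" not in raw.get("paths", {}):
        problems.append("missing required key: paths.output_dir")
    return problems


def load_config(path: str | Path) -> PipelineConfig:
    problems = validate_config(path)
    if problems:
        raise ValueError(f"invalid config {path}: " + "; ".join(problems))
    raw = yaml.safe_load(Path(path).read_text())
    win = raw.get("window", {})
    window = ObservationWindow(
        t_start=float(win.get("t_start", DEFAULT_WINDOW.t_start)),
        t_max=float(win.get("t_max", DEFAULT_WINDOW.t_max)),
    )
    paths = raw["paths"]
    return PipelineConfig(
        stages=list(raw["stages"]),
        output_dir=Path(paths["output_dir"]),
        rng_seed=int(raw.get("rng_seed", 0)),
        window=window,
        study_table=Path(paths["study_table"]) if "study_table" in paths else None,
        adoption_table=Path(paths["adoption_table"]) if "adoption_table" in paths else None,
        simulation=dict(raw.get("simulation", {})),
        accumulation=dict(raw.get("accumulation", {})),
        taxonomy=dict(raw.get("taxonomy", {})),
        propagation=dict(raw.get("propagation", {})),
        log_level=str(raw.get("log_level", "INFO")),
    )


def stage_seed(rng_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the global seed."""
    digest = hashlib.sha256(f"{rng_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulation_config(cfg: PipelineConfig) -> synthetic_data.SimulationConfig:
    s = cfg.simulation
    kwargs: dict[str, Any] = {"window": cfg.window, "rng_seed": stage_seed(cfg.rng_seed, "simulate")}
    if "n_diseases" in s:
        kwargs["n_diseases"] = s["n_diseases"]
    if "edge_density" in s:
        kwargs["edge_density"] = s["edge_density"]
    if "lambda_low" in s:
        kwargs["lambda_low"] = s["lambda_low"]
    if "lambda_high" in s:
        kwargs["lambda_high"] = s["lambda_high"]
    if "drugs_per_year" in s:
        kwargs["drugs_per_year"] = s["drugs_per_year"]
    if "year_start" in s or "year_end" in s:
        kwargs["year_span"] = (float(s.get("year_start", 1990)), float(s.get("year_end", 2010)))
    if "alpha_low" in s or "alpha_high" in s:
        kwargs["alpha_range"] = (float(s.get("alpha_low", 0.5)), float(s.get("alpha_high", 4.0)))
    if "beta_low" in s or "beta_high" in s:
        kwargs["beta_range"] = (float(s.get("beta_low", 0.7)), float(s.get("beta_high", 1.6)))
    return synthetic_data.SimulationConfig(**kwargs)


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Execute the configured stages in dependency order.

    Returns the manifest (relative path -> sha256) and writes it to
    ``manifest.json`` in the output directory.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    events: events_io.EventTable | None = None
    adoptions: tuple[events_io.AdoptionRecord, ...] | None = None

    def emit(path: Path) -> None:
        outputs.append(path)

    if "simulate" in cfg.stages:
        sim_cfg = _simulation_config(cfg)
        events, adoptions, truth = synthetic_data.simulate_dataset(sim_cfg)
        events_io.write_study_table(events, out / "studies.tsv")
        events_io.write_adoption_table(adoptions, out / "adoptions.tsv")
        pd.DataFrame(
            truth.lambda_true, index=truth.disease_ids, columns=truth.disease_ids
        ).to_csv(out / "lambda_true.tsv", sep="\t")
        pd.DataFrame(
            {
                "drug_id": sorted(truth.alpha_true),
                "alpha": [truth.alpha_true[d] for d in sorted(truth.alpha_true)],
                "beta": [truth.beta_true[d] for d in sorted(truth.beta_true)],
                "seed_disease": [truth.seed_assignments[d] for d in sorted(truth.alpha_true)],
                "birth": [truth.birth_times[d] for d in sorted(truth.alpha_true)],
            }
        ).to_csv(out / "ground_truth_drugs.tsv", sep="\t", index=False)
        emit(out / "studies.tsv")
        emit(out / "adoptions.tsv")
        emit(out / "lambda_true.tsv")
        emit(out / "ground_truth_drugs.tsv")

    if events is None and cfg.study_table is not None:
        if not cfg.study_table.exists():
            raise FileNotFoundError(f"study table not found: {cfg.study_table}")
        events = events_io.read_study_table(cfg.study_table, cfg.window)
    if adoptions is None:
        if cfg.adoption_table is not None:
            if not cfg.adoption_table.exists():
                raise FileNotFoundError(f"adoption table not found: {cfg.adoption_table}")
            adoptions = events_io.read_adoption_table(cfg.adoption_table)
        elif events is not None:
            adoptions = events_io.derive_adoptions(events)

    if "accumulate" in cfg.stages:
        if events is None:
            raise ValueError("accumulate stage requires a study table (or the simulate stage)")
        agg = cfg.accumulation.get("aggregator", "mean")
        curve_f = accumulation.aligned_curve(events, mode="studies", aggregator=agg, window=cfg.window)
        pd.DataFrame(
            {"age": curve_f.ages, "value": curve_f.values, "support": curve_f.support}
        ).to_csv(out / "curve_studies.tsv", sep="\t", index=False)
        emit(out / "curve_studies.tsv")
        curve_g = accumulation.aligned_curve(adoptions, mode="diseases", aggregator=agg, window=cfg.window)
        pd.DataFrame(
            {"age": curve_g.ages, "value": curve_g.values, "support": curve_g.support}
        ).to_csv(out / "curve_diseases.tsv", sep="\t", index=False)
        emit(out / "curve_diseases.tsv")
        fits = []
        for name, curve in (("studies", curve_f), ("diseases", curve_g)):
            try:
                fit = accumulation.fit_power_law(curve, min_age=cfg.accumulation.get("min_age", 1))
                fits.append((name, fit.alpha, fit.beta, fit.r_squared))
            except ValueError:
                logger.warning("power-law fit skipped for %s curve (too few points)", name)
        pd.DataFrame(fits, columns=["curve", "alpha", "beta", "r_squared"]).to_csv(
            out / "power_law_fits.tsv", sep="\t", index=False
        )
        emit(out / "power_law_fits.tsv")
        ratio = accumulation.studies_per_drug_by_year(events)
        ratio.to_csv(out / "studies_per_drug.tsv", sep="\t")
        emit(out / "studies_per_drug.tsv")

    if "taxonomy" in cfg.stages:
        if adoptions is None:
            raise ValueError("taxonomy stage requires an adoption table")
        sets = taxonomy.build_drug_sets(adoptions, min_drugs=cfg.taxonomy.get("min_drugs", 50))
        sim = taxonomy.mi_similarity_matrix(sets)
        sim.to_csv(out / "mi_similarity.tsv", sep="\t")
        emit(out / "mi_similarity.tsv")
        dist = taxonomy.mi_to_distance(sim)
        dist.to_csv(out / "mi_distance.tsv", sep="\t")
        emit(out / "mi_distance.tsv")
        if len(sets.diseases) >= 2:
            tree = taxonomy.ward_cluster(dist)
            taxonomy.export_newick(tree, out / "taxonomy.nwk")
            emit(out / "taxonomy.nwk")
        excl = taxonomy.exclusivity(sets)
        excl.to_csv(out / "exclusivity.tsv", sep="\t")
        emit(out / "exclusivity.tsv")

    if "network" in cfg.stages:
        if adoptions is None:
            raise ValueError("network stage requires an adoption table")
        model = cfg.propagation.get("model", "pairwise")
        t_cut = float(cfg.propagation.get("t_cut", propagation.DEFAULT_T_CUT))
        estimates = propagation.infer_network_rates(adoptions, window=cfg.window, model=model)
        rows = [
            {
                "source": i,
                "target": j,
                "lambda_hat": est.lambda_hat,
                "t_hat": est.t_hat,
                "n_observed": est.n_observed,
                "n_censored": est.n_censored,
            }
            for (i, j), est in sorted(estimates.items())
        ]
        pd.DataFrame(rows, columns=["source", "target", "lambda_hat", "t_hat", "n_observed", "n_censored"]).to_csv(
            out / "edges.tsv", sep="\t", index=False
        )
        emit(out / "edges.tsv")
        net = propagation.build_network(estimates, t_cut=t_cut)
        metrics = propagation.path_metrics(net)
        metrics.table.to_csv(out / "path_metrics.tsv", sep="\t")
        emit(out / "path_metrics.tsv")

    manifest = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
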