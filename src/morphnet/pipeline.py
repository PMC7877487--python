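"""End-to-end run: simulate -> build networks -> train -> Grad-CAM -> evaluate.

A single YAML (or in-memory) configuration drives every stage; the run writes
all artifacts plus a manifest with the effective configuration, every seed,
content hashes of the artifacts and the headline metrics.  Rerunning an
identical configuration reproduces an identical manifest apart from file
paths and timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import evaluation, gradcam, synthetic
from .classifier import (
    Hyperparameters,
    labels_from_phenotypes,
    make_cv_plan,
    train,
)
from .network import NetworkConfig, build_network, save_network
from .nn import ModelConfig

log = logging.getLogger("morphnet")


@dataclass
class SimulationSection:
    grid: int = 48
    n_regions: int = 116
    n_asd: int = 30
    n_tc: int = 30
    shift_magnitude: float = 0.5
    noise_sd: float = 0.02
    save_volumes: bool = False


@dataclass
class NetworkSection:
    grid_size: int = 128
    bandwidth_rule: str | float = "silverman"
    exclude_vermis: bool = True


@dataclass
class ModelSection:
    channels_per_stage: tuple[int, ...] = (16, 32, 64, 128, 256)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 20
    early_stop_patience: int = 5


@dataclass
class CVSection:
    n_folds: int = 5
    n_repeats: int = 2


@dataclass
class EvaluationSection:
    baselines: tuple[str, ...] = ("RF", "SVM", "XGB", "AE")
    n_perm: int = 99
    flip_fraction: float = 0.2
    run_gradcam: bool = True
    k_sd: float = 3.0
    ae_hidden: tuple[int, ...] = (128, 16)
    ae_epochs: int = 10


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "morphnet_run"
    simulation: SimulationSection = field(default_factory=SimulationSection)
    network: NetworkSection = field(default_factory=NetworkSection)
    model: ModelSection = field(default_factory=ModelSection)
    cv: CVSection = field(default_factory=CVSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)

    def validate(self) -> None:
        sim, cv = self.simulation, self.cv
        if sim.n_asd < 1 or sim.n_tc < 1:
            raise ValueError("cohort sizes must be >= 1")
        if sim.n_asd + sim.n_tc < cv.n_folds:
            raise ValueError(
                f"folds ({cv.n_folds}) exceed subjects ({sim.n_asd + sim.n_tc})"
            )
        if not (0 < self.evaluation.flip_fraction < 1):
            raise ValueError("flip_fraction must be in (0, 1)")
        NetworkConfig(grid_size=self.network.grid_size)  # raises if invalid

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "simulation": SimulationSection,
            "network": NetworkSection,
            "model": ModelSection,
            "cv": CVSection,
            "evaluation": EvaluationSection,
        }
        kwargs: dict = {}
        for key, val in raw.items():
            if key in sections:
                sub = sections[key](**val)
                for f_name in ("channels_per_stage", "baselines", "ae_hidden"):
                    if hasattr(sub, f_name):
                        setattr(sub, f_name, tuple(getattr(sub, f_name)))
                kwargs[key] = sub
            elif key in ("seed", "out_dir"):
                kwargs[key] = val
            else:
                raise ValueError(f"unknown config section '{key}'")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    config.validate()
    t0 = time.time()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    artifacts: dict[str, str] = {}

    log.info("stage 1/5: simulating cohort")
    sim = config.simulation
    atlas = synthetic.generate_atlas(
        (sim.grid,) * 3, n_regions=sim.n_regions, seed=config.seed
    )
    effect = synthetic.default_effect(sim.shift_magnitude, n_regions=sim.n_regions)
    effect.noise_sd = sim.noise_sd
    gm_maps, phenotypes = synthetic.simulate_cohort(
        atlas, sim.n_asd, sim.n_tc, effect, seed=config.seed
    )
    pheno_path = os.path.join(out, "phenotypes.csv")
    phenotypes.to_csv(pheno_path, index=False)
    artifacts["phenotypes"] = pheno_path
    if sim.save_volumes:
        vol_paths = synthetic.save_cohort(gm_maps, phenotypes, atlas, os.path.join(out, "volumes"))
        artifacts.update({f"volume:{k}": v for k, v in vol_paths.items()})

    log.info("stage 2/5: building %d morphological networks", len(gm_maps))
    net_cfg = NetworkConfig(
        excluded_labels=(
            frozenset(range(109, 117)) if config.network.exclude_vermis else frozenset()
        ),
        grid_size=config.network.grid_size,
        bandwidth_rule=config.network.bandwidth_rule,
    )
    networks = [build_network(gm, atlas, net_cfg) for gm in gm_maps]
    net_dir = os.path.join(out, "networks")
    os.makedirs(net_dir, exist_ok=True)
    for net in networks:
        p = os.path.join(net_dir, f"{net.subject_id}.tsv")
        save_network(net, p, sidecar=False)
        artifacts[f"network:{net.subject_id}"] = p

    log.info("stage 3/5: training CNN (%d folds x %d repeats)",
             config.cv.n_folds, config.cv.n_repeats)
    plan = make_cv_plan(
        phenotypes, n_folds=config.cv.n_folds, n_repeats=config.cv.n_repeats,
        seed=config.seed,
    )
    model_cfg = ModelConfig(
        input_size=networks[0].n_regions,
        channels_per_stage=tuple(config.model.channels_per_stage),
        seed=config.seed,
    )
    hyper = Hyperparameters(
        learning_rate=config.model.learning_rate,
        batch_size=config.model.batch_size,
        max_epochs=config.model.max_epochs,
        early_stop_patience=config.model.early_stop_patience,
    )
    models, fold_results = train(networks, phenotypes, plan, model_cfg, hyper)
    fr_path = os.path.join(out, "fold_results.csv")
    fold_results.to_csv(fr_path, index=False)
    artifacts["fold_results"] = fr_path
    logs = pd.concat(
        [m.training_log.assign(repeat=r) for r, m in models.items()],
        ignore_index=True,
    )
    log_path = os.path.join(out, "training_log.csv")
    logs.to_csv(log_path, index=False)
    artifacts["training_log"] = log_path

    log.info("stage 4/5: Grad-CAM")
    selection_summary = None
    if config.evaluation.run_gradcam:
        maps = gradcam.maps_for_correct_asd(models, networks, fold_results)
        if maps:
            fused = gradcam.fuse_maps(maps)
            sel = gradcam.select_connectivities(
                fused, networks[0].region_labels, k_sd=config.evaluation.k_sd
            )
            fmap_path = os.path.join(out, "fused_gradcam.tsv")
            np.savetxt(fmap_path, fused.matrix, delimiter="\t")
            artifacts["fused_gradcam"] = fmap_path
            sel_path = os.path.join(out, "selected_connectivities.csv")
            names = atlas.label_names
            with open(sel_path, "w") as fh:
                fh.write("region_a,region_b,name_a,name_b,weight\n")
                for a, b, w in sel.edges:
                    fh.write(f"{a},{b},{names.get(a, a)},{names.get(b, b)},{w:.8g}\n")
            artifacts["selected_connectivities"] = sel_path
            selection_summary = {
                "n_edges": len(sel.edges),
                "n_regions": len(sel.region_set),
                "threshold": sel.threshold,
                "n_maps_fused": len(maps),
            }

    log.info("stage 5/5: evaluation")
    y = labels_from_phenotypes(phenotypes).astype(int)
    cnn_metrics = evaluation.compute_metrics(
        fold_results["label"], fold_results["score"]
    )
    baseline_reports = {}
    if config.evaluation.baselines:
        baseline_reports = evaluation.run_baselines(
            networks, y, plan, methods=config.evaluation.baselines,
            seed=config.seed,
            ae_hidden=tuple(config.evaluation.ae_hidden),
            ae_epochs=config.evaluation.ae_epochs,
        )
    features = evaluation.flatten_networks(networks)
    perm = evaluation.permutation_test(
        evaluation.make_logistic_surrogate(seed=config.seed),
        features,
        y,
        n_perm=config.evaluation.n_perm,
        flip_fraction=config.evaluation.flip_fraction,
        seed=config.seed,
    )
    roc_path = os.path.join(out, "roc_points.csv")
    evaluation.roc_curve_points(fold_results["label"], fold_results["score"]).to_csv(
        roc_path, index=False
    )
    artifacts["roc_points"] = roc_path
    comparison = pd.DataFrame(
        [{"method": "CNN", **cnn_metrics.as_dict()}]
        + [{"method": k, **v.as_dict()} for k, v in baseline_reports.items()]
    )
    cmp_path = os.path.join(out, "comparison_table.csv")
    comparison.to_csv(cmp_path, index=False)
    artifacts["comparison_table"] = cmp_path
    perm_path = os.path.join(out, "permutation_null.csv")
    np.savetxt(perm_path, perm.null_accuracies, delimiter=",",
               header="null_accuracy", comments="")
    artifacts["permutation_null"] = perm_path

    metrics = {
        "cnn": cnn_metrics.as_dict(),
        "baselines": {k: v.as_dict() for k, v in baseline_reports.items()},
        "permutation": {
            "observed_accuracy": perm.observed_accuracy,
            "empirical_p": perm.empirical_p,
            "n_perm": config.evaluation.n_perm,
            "flip_fraction": perm.flip_fraction,
        },
        "gradcam_selection": selection_summary,
    }
    metrics_path = os.path.join(out, "metrics.json")
    with open(metrics_path, "w") as fh:
        json.dump(metrics, fh, indent=2)
    artifacts["metrics"] = metrics_path

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "cv_partition_hash": plan.partition_hash(),
        "metrics": metrics,
        "artifacts": {k: {"path": v, "sha256": _sha256(v)} for k, v in artifacts.items()},
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
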