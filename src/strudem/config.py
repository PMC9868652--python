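"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` bundles per-stage settings; every stage's random
seed is derived deterministically by hashing (global seed, stage name),
so re-running any stage is independent of execution order. The pipeline
executes simulate -> prep -> train/evaluate -> entropy -> explain ->
trends and writes a manifest (config hash, stage outputs and their
hashes) from which any derived output is regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .entropy import cluster_embeddings, contingency_from_labels, total_entropy
from .explain import accumulated_shap, composite_importance, layer_shap
from .io import write_tables
from .models import ModelSpec
from .prep import PropensityMatcher, make_prediagnosis, tensorize
from .simulate import GeneratorConfig, generate_cohort
from .taxonomy import pancreas_panel, toy_taxonomy
from .train import TrainConfig, early_detection_sweep, train_eval
from .trends import group_trends

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

logger = logging.getLogger(__name__)

_REQUIRED_STAGES = ("simulate", "prep", "model", "train")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/demo"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=lambda: dict(
        n_cases=50, n_controls=50, lookback_months=24.0, visit_rate=12.0,
        missingness=0.6, drift_per_month=0.15,
        signal_groups=["liver function group"],
        taxonomy="panel", n_variables=206,
    ))
    prep: dict = field(default_factory=lambda: dict(
        n_bins=24, bin_width_months=1.0, propensity=True,
        censor_months=[0, 3, 6, 12],
    ))
    model: dict = field(default_factory=lambda: dict(
        levels=["base", "combo", "composite"], strategy="g1", embed_hidden=16,
    ))
    train: dict = field(default_factory=lambda: dict(
        n_repeats=3, test_fraction=0.2, max_epochs=50, patience=5,
        learning_rate=1e-3, batch_size=32,
    ))
    entropy: dict = field(default_factory=lambda: dict(n_components=2))
    explain: dict = field(default_factory=lambda: dict(
        background_size=50, n_permutations=16, importance_repeats=10,
        explain_size=50, levels=[2, 3],
    ))
    trends: dict = field(default_factory=lambda: dict(
        anchors=[0.0, 3.0, 6.0, 12.0], half_window=2.0,
    ))

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        missing = [s for s in _REQUIRED_STAGES if s not in d]
        if missing:
            raise ValueError(f"config missing required stage block(s): {missing}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                kwargs[f.name] = d[f.name]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_taxonomy(sim: dict):
    kind = sim.get("taxonomy", "panel")
    if kind == "panel":
        return pancreas_panel(int(sim.get("n_variables", 206)))
    if kind == "toy":
        return toy_taxonomy(
            n_variables=int(sim.get("n_variables", 10)),
            n_combos=int(sim.get("n_combos", 5)),
            n_composites=int(sim.get("n_composites", 2)),
        )
    raise ValueError(f"unknown taxonomy kind {kind!r}")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    manifest: dict = {
        "config_hash": config.content_hash(),
        "version": __version__,
        "stages": {},
    }
    stage = "simulate"
    try:
        tax = _build_taxonomy(config.simulate)
        sim = {k: v for k, v in config.simulate.items()
               if k not in ("taxonomy", "n_variables", "n_combos", "n_composites")}
        if "signal_groups" in sim:
            sim["signal_groups"] = tuple(sim["signal_groups"])
        gen = GeneratorConfig(taxonomy=tax, seed=stage_seed(config.seed, "simulate"),
                              **sim)
        records, cohort, ranges = generate_cohort(gen)
        paths = write_tables(outdir / "data", records, cohort, ranges)
        manifest["stages"]["simulate"] = {
            "n_records": int(len(records)),
            "n_patients": int(len(cohort)),
            "outputs": {k: _file_hash(Path(p)) for k, p in paths.items()},
        }

        stage = "prep"
        pre = make_prediagnosis(records, cohort)
        if config.prep.get("propensity", True):
            matcher = PropensityMatcher(
                random_state=stage_seed(config.seed, "prep")).fit(cohort)
            cohort_m = matcher.matched_cohort_
            pre_m = pre[pre["patient_id"].isin(set(cohort_m["patient_id"]))]
            manifest["stages"]["prep"] = {
                "pre_match_separability": matcher.result_.pre_match_separability,
                "post_match_separability": matcher.result_.post_match_separability,
            }
        else:
            cohort_m, pre_m = cohort, pre
            manifest["stages"]["prep"] = {}
        tc = tensorize(pre_m, cohort_m, tax, int(config.prep["n_bins"]),
                       float(config.prep.get("bin_width_months", 1.0)))
        manifest["stages"]["prep"].update(
            n_patients=len(tc.patients), n_bins=tc.n_bins)

        stage = "train"
        tcfg = TrainConfig(seed=stage_seed(config.seed, "train"),
                           **{k: v for k, v in config.train.items()})
        strategy = config.model.get("strategy", "g1")
        results = {}
        composite_result = None
        for level in config.model["levels"]:
            spec = ModelSpec(level=level,
                             strategy=strategy if level == "composite" else None,
                             embed_hidden=int(config.model.get("embed_hidden", 16)))
            res = train_eval(spec, tax, tc, tcfg, keep_models=True)
            results[level] = res
            if level == "composite":
                composite_result = res
        manifest["stages"]["train"] = {
            lvl: res.summary() for lvl, res in results.items()
        }

        stage = "evaluate"
        sweep = {}
        if composite_result is not None and config.prep.get("censor_months"):
            model0 = composite_result.models[0]
            _, te = composite_result.splits[0]
            sweep = early_detection_sweep(
                model0, pre_m, cohort_m,
                [float(k) for k in config.prep["censor_months"]],
                tax, tc.n_bins, float(config.prep.get("bin_width_months", 1.0)),
                eval_patients=te, reference=tc,
            )
        manifest["stages"]["evaluate"] = {str(k): v for k, v in sweep.items()}

        stage = "entropy"
        ent = {}
        eseed = stage_seed(config.seed, "entropy")
        for level, res in results.items():
            emb = res.models[0].embeddings(tc.values).final
            labels = cluster_embeddings(
                emb, int(config.entropy.get("n_components", 2)), seed=eseed)
            ent[level] = total_entropy(contingency_from_labels(labels, tc.labels))
        manifest["stages"]["entropy"] = ent

        stage = "explain"
        manifest["stages"]["explain"] = {}
        if composite_result is not None:
            model0 = composite_result.models[0]
            emb = model0.embeddings(tc.values)
            xseed = stage_seed(config.seed, "explain")
            imp = composite_importance(
                emb.level3, tc.labels, model0.composites_,
                n_repeats=int(config.explain.get("importance_repeats", 10)),
                seed=xseed)
            shap_rep = layer_shap(
                model0, tc.values,
                background_size=int(config.explain.get("background_size", 50)),
                explain_size=config.explain.get("explain_size"),
                n_permutations=int(config.explain.get("n_permutations", 16)),
                seed=xseed,
                levels=tuple(config.explain.get("levels", [2, 3])),
            )
            imp.scores.to_csv(outdir / "importance.csv", index=False)
            for lvl, t in shap_rep.tables.items():
                t.to_csv(outdir / f"shap_level{lvl}.csv", index=False)
            manifest["stages"]["explain"] = {
                "top_composite_by_rf": imp.ranking("random_forest")[0],
                "top_level3_shap": shap_rep.ranking(max(shap_rep.tables))[0],
            }
            if 1 in shap_rep.tables:
                acc = accumulated_shap(shap_rep.tables[1], tax, strategy)
                acc.to_csv(outdir / "accumulated_shap.csv", index=False)

        stage = "trends"
        tr = group_trends(records, cohort, ranges,
                          anchors=tuple(config.trends.get("anchors",
                                                          (0, 3, 6, 12))),
                          half_window=float(config.trends.get("half_window", 2.0)))
        tr.to_csv(outdir / "trends.csv", index=False)
        manifest["stages"]["trends"] = {"n_rows": int(len(tr))}
    except Exception as exc:
        (outdir / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
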