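"""End-to-end pipeline: simulate -> preprocess -> annotate -> encode ->
train -> evaluate -> explain, with per-stage manifests and caching.

A run directory accumulates one subdirectory per stage plus a
``manifest.json`` recording, for every stage, the hash of its configuration
and inputs, its outputs and timing. Re-running with unchanged inputs skips
completed stages; tampering with the encoded-tensor container is detected by
hash comparison before training.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotateConfig, FEATURE_SLOTS, annotate_dataset, fit_norm_stats, apply_norm_stats, NormStats
from .encode import EncoderConfig, SampleSet, encode_dataset
from .io import (
    read_epitracks,
    read_screen_table,
    write_screen_table,
    write_track_bedgraph,
    write_tss_table,
)
from .model import EvalReport, ModelConfig, SplitPlan, TrainedModel, evaluate, grouped_train_test_split, train
from .preprocess import PreprocessConfig, assign_labels, compute_activity_scores, transform_scores
from .interpret import deep_attribution, engineer_features, tree_importance
from .simulate import preset, simulate_screen

STAGES = ("simulate", "preprocess", "annotate", "encode", "train", "evaluate", "explain")

#: recognised top-level configuration keys
CONFIG_KEYS = {"seed", "name", *STAGES}


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def validate_config(config: dict) -> dict:
    unknown = set(config) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    for stage in STAGES:
        cfg.setdefault(stage, {})
        if not isinstance(cfg[stage], dict):
            raise ValueError(f"configuration section {stage!r} must be a mapping")
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: Dict[str, dict] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "seed": self.seed,
                 "version": self.version, "stages": self.stages},
                fh, indent=2,
            )

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config_hash=d["config_hash"], seed=d["seed"],
                   version=d["version"], stages=d["stages"])


class PipelineRun:
    """Stage executor with manifest-based caching over a run directory."""

    def __init__(self, config: dict, outdir):
        self.config = validate_config(config)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = RunManifest.load(self.manifest_path)
        else:
            self.manifest = RunManifest(
                config_hash=_hash_obj(self.config), seed=self.config["seed"], version=__version__
            )

    # ------------------------------------------------------------------ caching

    def _stage_key(self, stage: str, input_files: List[Path]) -> str:
        return _hash_obj(
            {
                "config": self.config.get(stage, {}),
                "seed": self.config["seed"],
                "inputs": {str(p): _hash_file(p) for p in input_files},
            }
        )

    def _is_cached(self, stage: str, key: str) -> bool:
        entry = self.manifest.stages.get(stage)
        if entry is None or entry.get("key") != key:
            return False
        return all(Path(p).exists() for p in entry["outputs"])

    def _record(self, stage: str, key: str, outputs: List[Path], elapsed: float, cached: bool) -> None:
        self.manifest.stages[stage] = {
            "key": key,
            "outputs": [str(p) for p in outputs],
            "elapsed_s": round(elapsed, 3),
            "cached": cached,
        }
        self.manifest.save(self.manifest_path)

    def _run_stage(self, stage: str, input_files: List[Path], fn) -> List[Path]:
        key = self._stage_key(stage, input_files)
        if self._is_cached(stage, key):
            self._record(stage, key, [Path(p) for p in self.manifest.stages[stage]["outputs"]],
                         0.0, cached=True)
            return [Path(p) for p in self.manifest.stages[stage]["outputs"]]
        t0 = time.perf_counter()
        outputs = fn()
        self._record(stage, key, outputs, time.perf_counter() - t0, cached=False)
        return outputs

    # ------------------------------------------------------------------- stages

    def stage_simulate(self) -> List[Path]:
        d = self.outdir / "simulate"

        def run():
            d.mkdir(exist_ok=True)
            sc = self.config["simulate"]
            cfg = preset(sc.get("preset", "smoke"), seed=self.config["seed"],
                         epi_level=sc.get("epi_level", 1.0),
                         **{k: v for k, v in sc.items() if k not in ("preset", "epi_level")})
            dataset, tracks, truth = simulate_screen(cfg)
            write_screen_table(dataset, d / "screen.tsv")
            tracks.genome.to_fasta(d / "genome.fa")
            write_tss_table(tracks.tss_table, d / "tss.tsv")
            write_track_bedgraph(tracks.atac, d / "atac.bedgraph")
            write_track_bedgraph(tracks.methylation, d / "methylation.bedgraph")
            write_track_bedgraph(tracks.expression, d / "expression.bedgraph")
            truth.to_csv(d / "truth.tsv", sep="\t")
            return [d / n for n in ("screen.tsv", "genome.fa", "tss.tsv", "atac.bedgraph",
                                    "methylation.bedgraph", "expression.bedgraph", "truth.tsv")]

        return self._run_stage("simulate", [], run)

    def stage_preprocess(self, screen_tsv: Path) -> List[Path]:
        d = self.outdir / "preprocess"

        def run():
            d.mkdir(exist_ok=True)
            pc = self.config["preprocess"]
            cfg = PreprocessConfig(
                top_k=pc.get("top_k", 3),
                phenotype_label_cutoff=pc.get("phenotype_cutoff", -0.1),
                activity_label_cutoff=pc.get("activity_cutoff", 0.75),
                genewise_normalization=pc.get("genewise", True),
            )
            dataset = read_screen_table(screen_tsv, direction=pc.get("direction", "silencing"))
            labels = assign_labels(dataset, cfg)           # phenotype rule, raw scale
            transformed = transform_scores(dataset)
            activity, report = compute_activity_scores(transformed, cfg)
            df = pd.read_csv(screen_tsv, sep="\t")
            df["activity"] = activity.scores()
            df["label"] = labels
            df.to_csv(d / "screen_activity.tsv", sep="\t", index=False)
            with open(d / "report.json", "w") as fh:
                json.dump(
                    {"n_missing_score": report.n_missing_score,
                     "undefined_activity_ids": report.undefined_activity_ids},
                    fh, indent=2,
                )
            return [d / "screen_activity.tsv", d / "report.json"]

        return self._run_stage("preprocess", [screen_tsv], run)

    def stage_annotate(self, screen_tsv: Path, sim_dir: Path) -> List[Path]:
        d = self.outdir / "annotate"
        inputs = [screen_tsv] + [sim_dir / n for n in
                                 ("genome.fa", "tss.tsv", "atac.bedgraph",
                                  "methylation.bedgraph", "expression.bedgraph")]

        def run():
            d.mkdir(exist_ok=True)
            ac = self.config["annotate"]
            cfg = AnnotateConfig(methylation_window=ac.get("meth_window", 100))
            dataset = read_screen_table(screen_tsv)
            tracks = read_epitracks(sim_dir / "genome.fa", sim_dir / "tss.tsv",
                                    sim_dir / "atac.bedgraph", sim_dir / "methylation.bedgraph",
                                    sim_dir / "expression.bedgraph")
            raw = annotate_dataset(dataset, tracks, cfg)
            stats = fit_norm_stats(raw)
            norm = apply_norm_stats(raw, stats)
            norm.to_csv(d / "features.tsv", sep="\t", index_label="sgrna_id")
            stats.to_json(d / "normstats.json")
            return [d / "features.tsv", d / "normstats.json"]

        return self._run_stage("annotate", inputs, run)

    def stage_encode(self, screen_activity_tsv: Path, features_tsv: Path, sim_dir: Path,
                     report_json: Path) -> List[Path]:
        d = self.outdir / "encode"
        inputs = [screen_activity_tsv, features_tsv, sim_dir / "genome.fa", report_json]

        def run():
            d.mkdir(exist_ok=True)
            ec = self.config["encode"]
            cfg = EncoderConfig(
                context_length=ec.get("context_length", 40),
                channels=tuple(ec.get("channels", ("A", "C", "G", "T") + FEATURE_SLOTS)),
            )
            from .io import FastaGenome

            df = pd.read_csv(screen_activity_tsv, sep="\t")
            dataset = read_screen_table(screen_activity_tsv, score_col="activity")
            labels = df["label"].to_numpy(dtype=float)
            with open(report_json) as fh:
                exclude = json.load(fh)["undefined_activity_ids"]
            features = pd.read_csv(features_tsv, sep="\t", index_col="sgrna_id")
            genome = FastaGenome(sim_dir / "genome.fa")
            samples = encode_dataset(dataset, features, cfg, genome=genome,
                                     labels=labels, exclude_ids=exclude)
            np.savez(d / "encoded.npz", X=samples.X, targets=samples.targets,
                     labels=samples.labels, ids=np.array(samples.ids),
                     genes=np.array(samples.genes))
            man = {
                "channels": list(samples.channels),
                "context_length": cfg.context_length,
                "n_samples": len(samples),
                "tensor_sha256": _hash_file(d / "encoded.npz"),
            }
            with open(d / "encoded_manifest.json", "w") as fh:
                json.dump(man, fh, indent=2)
            return [d / "encoded.npz", d / "encoded_manifest.json"]

        return self._run_stage("encode", inputs, run)

    @staticmethod
    def load_samples(encode_dir: Path) -> SampleSet:
        """Load the encoded tensor container, refusing on hash mismatch."""
        man_path = Path(encode_dir) / "encoded_manifest.json"
        npz_path = Path(encode_dir) / "encoded.npz"
        with open(man_path) as fh:
            man = json.load(fh)
        actual = _hash_file(npz_path)
        if actual != man["tensor_sha256"]:
            raise ValueError(
                f"encoded tensor hash mismatch: manifest records "
                f"{man['tensor_sha256'][:12]}… but {npz_path.name} hashes to "
                f"{actual[:12]}…; refusing to train on tampered input"
            )
        with np.load(npz_path, allow_pickle=False) as z:
            return SampleSet(
                X=z["X"], targets=z["targets"], labels=z["labels"],
                ids=[str(s) for s in z["ids"]], genes=[str(s) for s in z["genes"]],
                channels=tuple(man["channels"]),
            )

    def stage_train(self, encode_dir: Path) -> List[Path]:
        d = self.outdir / "train"
        inputs = [encode_dir / "encoded.npz", encode_dir / "encoded_manifest.json"]

        def run():
            d.mkdir(exist_ok=True)
            tc = self.config["train"]
            samples = self.load_samples(encode_dir)
            cfg = ModelConfig(
                task=tc.get("task", "regression"),
                max_epochs=tc.get("max_epochs", 100),
                patience=tc.get("patience", 10),
                batch_size=tc.get("batch_size", 256),
                learning_rate=tc.get("learning_rate", 1e-3),
                seed=self.config["seed"],
            )
            split = SplitPlan(seed=self.config["seed"])
            model, report = train(samples, split, cfg)
            model.save(d / "model")
            with open(d / "eval.json", "w") as fh:
                json.dump(report.summary(), fh, indent=2)
            return [d / "model" / "weights.npz", d / "model" / "architecture.json",
                    d / "model" / "manifest.json", d / "eval.json"]

        return self._run_stage("train", inputs, run)

    def stage_evaluate(self, encode_dir: Path, train_dir: Path) -> List[Path]:
        d = self.outdir / "evaluate"
        inputs = [train_dir / "model" / "weights.npz", encode_dir / "encoded.npz"]

        def run():
            d.mkdir(exist_ok=True)
            samples = self.load_samples(encode_dir)
            model = TrainedModel.load(train_dir / "model")
            task = model.net.cfg.task
            y = samples.labels if task == "classification" else samples.targets
            ok = np.flatnonzero(~np.isnan(y))
            usable = samples.subset(ok)
            split = SplitPlan(seed=self.config["seed"])
            _, test_idx = grouped_train_test_split(usable.genes, split)
            te = usable.subset(test_idx)
            yte = te.labels if task == "classification" else te.targets
            rep = evaluate(model.predict(te.X), yte, task)
            rep.n_train = len(usable) - len(te)
            pred_df = pd.DataFrame({"sgrna_id": te.ids, "prediction": model.predict(te.X), "truth": yte})
            pred_df.to_csv(d / "predictions.tsv", sep="\t", index=False)
            with open(d / "metrics.json", "w") as fh:
                json.dump(rep.summary(), fh, indent=2)
            return [d / "metrics.json", d / "predictions.tsv"]

        return self._run_stage("evaluate", inputs, run)

    def stage_explain(self, encode_dir: Path, train_dir: Path, screen_activity_tsv: Path,
                      features_tsv: Path) -> List[Path]:
        d = self.outdir / "explain"
        inputs = [train_dir / "model" / "weights.npz", encode_dir / "encoded.npz",
                  screen_activity_tsv, features_tsv]

        def run():
            d.mkdir(exist_ok=True)
            xc = self.config["explain"]
            samples = self.load_samples(encode_dir)
            model = TrainedModel.load(train_dir / "model")
            attr = deep_attribution(
                model.net, samples.X,
                n=xc.get("n", 1000), n_background=xc.get("n_background", 100),
                steps=xc.get("steps", 16), seed=self.config["seed"],
            )
            attr.positional_map.to_csv(d / "positional_map.tsv", sep="\t")

            dataset = read_screen_table(screen_activity_tsv, score_col="activity")
            features = pd.read_csv(features_tsv, sep="\t", index_col="sgrna_id")
            keep = [r for r in dataset.records if r.raw_score is not None]
            if len(keep) >= 50:
                table = engineer_features(keep, epi=features.loc[[r.sgrna_id for r in keep]],
                                          tm_method=xc.get("tm_method", "nn"))
                targets = np.array([r.raw_score for r in keep])
                res = tree_importance(table, targets, seed=self.config["seed"])
                res.importance.rename("mean_abs_shap").to_csv(d / "importance.tsv", sep="\t")
            else:
                pd.Series(dtype=float, name="mean_abs_shap").to_csv(d / "importance.tsv", sep="\t")
            return [d / "positional_map.tsv", d / "importance.tsv"]

        return self._run_stage("explain", inputs, run)

    # ---------------------------------------------------------------------- all

    def run(self) -> RunManifest:
        sim_dir = self.outdir / "simulate"
        self.stage_simulate()
        self.stage_preprocess(sim_dir / "screen.tsv")
        pre_dir = self.outdir / "preprocess"
        self.stage_annotate(pre_dir / "screen_activity.tsv", sim_dir)
        ann_dir = self.outdir / "annotate"
        self.stage_encode(pre_dir / "screen_activity.tsv", ann_dir / "features.tsv",
                          sim_dir, pre_dir / "report.json")
        enc_dir = self.outdir / "encode"
        self.stage_train(enc_dir)
        self.stage_evaluate(enc_dir, self.outdir / "train")
        self.stage_explain(enc_dir, self.outdir / "train",
                           pre_dir / "screen_activity.tsv", ann_dir / "features.tsv")
        return self.manifest


def run_pipeline(config, outdir) -> RunManifest:
    """Execute the full pipeline from a config mapping or YAML file path."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    return PipelineRun(config, outdir).run()
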