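"""End-to-end orchestration: generate -> label -> train -> prune -> evaluate -> rules.

:func:`run_pipeline` executes all stages under one :class:`RunConfig`, writes
the five artifacts (generated CSV, labeled CSV, model JSON, rules text,
evaluation report JSON) plus a manifest with the config, seeds and artifact
hashes, and is byte-for-byte reproducible from the same config and seed.

The 20% test split is never shown to the learner; the cost-complexity
pruning holdout is carved out of the training portion instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .evaluation import split_train_test
from .model import RearingTreeModel
from .suitability import label_dataset
from .synthetic import GeneratorConfig, default_generator_config, generate_records
from .tree import TreeParams, tree_to_json
from .weight_tables import load_weight_config

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    outdir: str | Path
    seed: int = 0
    operator: str = "decision"
    generator: GeneratorConfig | None = None  # None = study-condition defaults
    weights_source: str | Path | None = None  # None = packaged tables
    train_fraction: float = 0.8
    #: fraction of the *training* portion held out for pruning selection
    prune_fraction: float = 0.25
    tree_params: TreeParams = field(default_factory=TreeParams)
    kappa_threshold: float = 0.60

    def to_dict(self) -> dict:
        gen = self.generator or default_generator_config(seed=self.seed)
        return {
            "seed": self.seed,
            "operator": self.operator,
            "generator": gen.to_dict(),
            "weights_source": None if self.weights_source is None else str(self.weights_source),
            "train_fraction": self.train_fraction,
            "prune_fraction": self.prune_fraction,
            "tree_params": {
                "min_leaf": self.tree_params.min_leaf,
                "max_depth": self.tree_params.max_depth,
                "attributes_per_node": self.tree_params.attributes_per_node,
                "seed": self.tree_params.seed,
                "min_support_fraction": self.tree_params.min_support_fraction,
            },
            "kappa_threshold": self.kappa_threshold,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the outdir)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gen_cfg = cfg.generator or default_generator_config(seed=cfg.seed)
    ds = _stage("generate")(generate_records, gen_cfg)
    generated_path = outdir / "generated.csv"
    ds.records.to_csv(generated_path, index=False)

    weights = _stage("load-weights")(load_weight_config, cfg.weights_source)
    labeled = _stage("label")(label_dataset, weights, ds.records)
    labeled_path = outdir / "labeled.csv"
    labeled.to_csv(labeled_path, index=False)

    train, test = _stage("split")(
        split_train_test, labeled, cfg.train_fraction, cfg.seed
    )
    fit_part, prune_part = _stage("split")(
        split_train_test, train, 1.0 - cfg.prune_fraction, cfg.seed + 1
    )

    def train_and_prune():
        results = RearingTreeModel(
            fit_part, operator=cfg.operator, params=cfg.tree_params
        ).fit()
        results = results.prune(prune_part)
        return results.prune_min_support()

    results = _stage("train")(train_and_prune)
    model_path = outdir / "model.json"
    tree_to_json(results.tree, model_path)

    rules_path = outdir / "rules.txt"
    rules_path.write_text(str(_stage("rules")(results.rules)) + "\n")

    report = _stage("evaluate")(results.evaluate, test, cfg.kappa_threshold)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")

    artifacts = {
        "generated": generated_path,
        "labeled": labeled_path,
        "model": model_path,
        "rules": rules_path,
        "report": report_path,
    }
    manifest = {
        "config": cfg.to_dict(),
        "seeds": {"pipeline": cfg.seed, "tree": cfg.tree_params.seed},
        "artifacts": {k: str(p) for k, p in artifacts.items()},
        "hashes": {k: _sha256(p) for k, p in artifacts.items()},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info(
        "pipeline complete: accuracy %.2f%%, kappa %.4f, %d leaves",
        report.accuracy,
        report.kappa,
        results.n_leaves,
    )
    return manifest
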