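"""End-to-end orchestration: encode -> split -> standardize -> train ->
evaluate -> attribute -> summarize, with reproducible on-disk artifacts.

A run is fully described by a :class:`RunConfig` (YAML-serializable).  One
global seed is fanned out into independent per-stage seeds so stages can be
rerun in isolation yet deterministically; every artifact a run writes is
listed in ``manifest.json`` with a content hash, and a rerun with the same
config and seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import encoding, metrics, schema as schema_mod, shapley, train as train_mod
from .model import GLNetConfig, load_checkpoint, predict_proba_batched, save_checkpoint
from .schema import FactorSchema, SchemaError

logger = logging.getLogger(__name__)

STAGES = ("encode", "train", "evaluate", "explain")


@dataclass
class RunConfig:
    input_csv: str
    out_dir: str
    seed: int = 0
    label_column: str = "depression"
    schema_overrides: dict = field(default_factory=dict)
    ordinal_factors: list = field(default_factory=lambda: [
        "academic_pressure", "work_pressure", "study_satisfaction",
        "job_satisfaction", "financial_stress"])
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.15
    # model
    embed_dim: int = 128
    ssm_state_dim: int = 16
    conv_kernel: int = 3
    # training
    epochs: int = 100
    lr: float = 1e-4
    batch_size: int = 256
    factor_dropout: float = 0.10
    shift_magnitude: float = 0.10
    early_stop_patience: int = 10
    weighted: bool = True
    # evaluation
    threshold: float = 0.5
    bootstrap_replicates: int = 1000
    # attribution
    background_size: int = 100
    explain_n: int = 256
    permutations: int = 200
    exact_limit: int = 15
    subgroup_factors: list = field(default_factory=lambda: ["gender", "degree"])
    min_subgroup: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.seed, idx]).generate_state(1)[0]
                   % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for blk in iter(lambda: fh.read(65536), b""):
            h.update(blk)
    return h.hexdigest()


def _json_write(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


class Run:
    """A run directory: owns artifact paths and shared data loading."""

    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.dir = Path(cfg.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        (self.dir / "subgroups").mkdir(exist_ok=True)

    def path(self, name: str) -> Path:
        return self.dir / name

    # -- shared data ------------------------------------------------------
    def load_schema(self) -> FactorSchema:
        p = self.path("schema.json")
        if p.exists():
            return FactorSchema.from_json(p)
        overrides = dict(self.cfg.schema_overrides)
        for name in self.cfg.ordinal_factors:
            overrides.setdefault(name, "ordinal")
        return schema_mod.infer_schema(self.cfg.input_csv, overrides,
                                       label_column=self.cfg.label_column)

    def load_encoded(self, sch: FactorSchema):
        records, dropped = schema_mod.load_records(self.cfg.input_csv, sch)
        ds = encoding.encode_dataset(records, sch)
        return records, ds, dropped

    # -- stages -----------------------------------------------------------
    def stage_encode(self) -> None:
        cfg = self.cfg
        sch = self.load_schema()
        sch.to_json(self.path("schema.json"))
        records, ds, dropped = self.load_encoded(sch)
        split = encoding.split_dataset(ds, cfg.test_fraction,
                                       cfg.val_fraction_of_train,
                                       seed=cfg.stage_seed("encode"))
        split.to_json(self.path("split.json"))
        std = encoding.fit_standardizer(ds, split.train)
        std.to_json(self.path("standardizer.json"))
        _json_write(self.path("encode_info.json"), {
            "n_records": ds.n, "n_dropped": dropped,
            "n_encoded_columns": len(ds.columns),
            "schema_id": ds.schema_id,
            "sizes": {"train": int(split.train.size),
                      "validation": int(split.validation.size),
                      "test": int(split.test.size)},
        })

    def _standardized(self):
        sch = FactorSchema.from_json(self.path("schema.json"))
        records, ds, _ = self.load_encoded(sch)
        split = encoding.SplitResult.from_json(self.path("split.json"))
        std = encoding.StandardizationParams.from_json(self.path("standardizer.json"))
        return sch, records, encoding.apply_standardizer(ds, std), split

    def stage_train(self) -> None:
        cfg = self.cfg
        _, _, ds, split = self._standardized()
        model_cfg = GLNetConfig(
            input_dim=len(ds.columns), embed_dim=cfg.embed_dim,
            ssm_state_dim=cfg.ssm_state_dim, conv_kernel=cfg.conv_kernel,
            seed=cfg.stage_seed("train"))
        train_cfg = train_mod.TrainConfig(
            lr=cfg.lr, batch_size=cfg.batch_size, epochs=cfg.epochs,
            factor_dropout=cfg.factor_dropout,
            shift_magnitude=cfg.shift_magnitude,
            seed=cfg.stage_seed("train"),
            early_stop_patience=cfg.early_stop_patience,
            weighted=cfg.weighted)
        model, history = train_mod.train_model(ds, split, model_cfg, train_cfg)
        save_checkpoint(model, self.path("checkpoint.bin"),
                        extra={"standardizer": _sha256(self.path("standardizer.json"))})
        _json_write(self.path("history.json"), history.to_dict())

    def stage_evaluate(self) -> None:
        cfg = self.cfg
        _, _, ds, split = self._standardized()
        model, _ = load_checkpoint(self.path("checkpoint.bin"))
        report = metrics.evaluate(model, ds, split.test,
                                  threshold=cfg.threshold,
                                  replicates=cfg.bootstrap_replicates,
                                  seed=cfg.stage_seed("evaluate"))
        report.to_json(self.path("metrics.json"))

    def stage_explain(self) -> None:
        cfg = self.cfg
        sch, records, ds, split = self._standardized()
        model, _ = load_checkpoint(self.path("checkpoint.bin"))
        rng = np.random.default_rng(cfg.stage_seed("explain"))
        explain_idx = np.sort(rng.choice(
            split.test, size=min(cfg.explain_n, split.test.size), replace=False))
        bg_idx = np.sort(rng.choice(
            split.train, size=min(cfg.background_size, split.train.size),
            replace=False))
        result = shapley.attribute_dataset(
            model, ds.matrix[explain_idx], ds.matrix[bg_idx], ds.columns,
            M=cfg.permutations, seed=cfg.stage_seed("explain"),
            limit=cfg.exact_limit)
        pd.DataFrame(result.phi, index=explain_idx, columns=ds.columns) \
            .to_csv(self.path("attributions.csv"), index_label="row")
        _json_write(self.path("attribution_meta.json"), {
            "base_value": result.base_value,
            "estimator": result.estimator,
            "config": result.config,
            "explained_rows": explain_idx.tolist(),
            "background_rows": bg_idx.tolist(),
        })
        values = ds.matrix[explain_idx]
        shapley.global_summary(result, values) \
            .to_csv(self.path("global_summary.csv"), index=False)
        shapley.beeswarm_export(result, values) \
            .to_csv(self.path("beeswarm.tsv"), sep="\t", index=False)
        # subgroup summaries on raw factor levels
        raw = records.iloc[explain_idx]
        for name in cfg.subgroup_factors:
            if name not in sch:
                continue
            for level in sch[name].levels:
                mask = raw[name].astype(str).to_numpy() == level
                if mask.sum() < cfg.min_subgroup:
                    continue
                summ = shapley.subgroup_attribution(
                    result, values, mask, description=f"{name}={level}",
                    min_size=cfg.min_subgroup)
                _json_write(self.path(f"subgroups/{name}={level}.json"),
                            summ.to_dict())

    def write_manifest(self) -> dict:
        artifacts = {}
        for p in sorted(self.dir.rglob("*")):
            if p.is_file() and p.name != "manifest.json":
                artifacts[str(p.relative_to(self.dir))] = _sha256(p)
        manifest = {"seed": self.cfg.seed, "artifacts": artifacts}
        _json_write(self.path("manifest.json"), manifest)
        return manifest


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return the artifact manifest."""
    run = Run(cfg)
    cfg.to_yaml(run.path("config.yaml"))
    failed = None
    try:
        for stage in STAGES:
            getattr(run, f"stage_{stage}")()
    except Exception:
        failed = stage
        raise
    finally:
        manifest = run.write_manifest()
        if failed is not None:
            manifest["failed_stage"] = failed
            _json_write(run.path("manifest.json"), manifest)
    return manifest


def subgroup_from_run(run_dir: str | Path, filter_expr: str,
                      min_size: int | None = None) -> shapley.SubgroupSummary:
    """Compute a subgroup summary for ``factor=value`` on a completed run."""
    run_dir = Path(run_dir)
    cfg = RunConfig.from_yaml(run_dir / "config.yaml")
    if min_size is not None:
        cfg.min_subgroup = min_size
    sch = FactorSchema.from_json(run_dir / "schema.json")
    if "=" not in filter_expr:
        raise ValueError("filter must look like factor=value")
    name, level = filter_expr.split("=", 1)
    if name not in sch:
        raise SchemaError(
            f"unknown factor {name!r}; valid factors: {sch.names}")
    meta = json.loads((run_dir / "attribution_meta.json").read_text())
    att = pd.read_csv(run_dir / "attributions.csv", index_col="row")
    result = shapley.AttributionResult(
        att.to_numpy(), meta["base_value"], list(att.columns),
        meta["estimator"], meta["config"])
    records, _ = schema_mod.load_records(cfg.input_csv, sch)
    raw = records.iloc[np.asarray(meta["explained_rows"])]
    mask = raw[name].astype(str).to_numpy() == level
    std = encoding.StandardizationParams.from_json(run_dir / "standardizer.json")
    ds = encoding.apply_standardizer(
        encoding.encode_dataset(records, sch), std)
    values = ds.matrix[np.asarray(meta["explained_rows"])]
    summ = shapley.subgroup_attribution(result, values, mask,
                                        description=filter_expr,
                                        min_size=cfg.min_subgroup)
    _json_write(run_dir / "subgroups" / f"{name}={level}.json", summ.to_dict())
    return summ
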