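"""Run configuration: YAML parsing, object builders, seeds and manifests.

A single key-value configuration file drives every subcommand.  Sections:

```yaml
seed: 7
outcome_column: los_days
data:                       # exactly one source
  synthetic: {n: 4000}      #   generator spec overrides, or
  # csv: cohort.csv         #   a delimited feature table
schema:
  categorical: [sex, race]  # optional: columns forced to categorical
  exclude: [encounter_id]   # identifier columns dropped before modeling
split: {train_fraction: 0.6667, cv_folds: 5}
two_stage:
  tau_c: 7.0
  tau_r: 35.0
  target_short_sensitivity: 0.99
  stage2_transform: log
  classifier: {family: tree_ensemble, hyperparameters: {n_estimators: 100}}
  regressor:  {family: tree_ensemble}
grid:
  approaches: [one_stage, two_stage]
  algorithms: [{family: penalized_linear}, {family: tree_ensemble}]
  transforms: [identity, log, {kind: truncate, level: 7}]
  losses: [mse, mae, customized]
evaluate:
  bootstrap: {B: 500, level: 0.95}
sweep:
  taus: [7, 21, 35]
```

CLI flags override file values.  Every run writes a manifest (config hash,
seed, package version) sufficient to reproduce it exactly; manifests carry no
timestamps so same-seed reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import ComparisonGrid, SplitSpec
from .learners import LearnerSpec
from .synthetic import CohortSpec, generate_cohort
from .transforms import OutcomeTransform
from .two_stage import TwoStageConfig

__all__ = [
    "RunConfig",
    "load_config",
    "derive_seed",
    "transform_from",
    "learner_spec_from",
    "write_manifest",
]


def derive_seed(base: int, *tags: str) -> int:
    """Deterministic child seed (< 2**31) for a named randomness consumer."""
    entropy = [int(base)] + [zlib.crc32(t.encode()) for t in tags]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


def transform_from(value) -> OutcomeTransform:
    if isinstance(value, OutcomeTransform):
        return value
    if isinstance(value, str):
        name = value.strip().lower()
        if name == "identity":
            return OutcomeTransform.identity()
        if name == "log":
            return OutcomeTransform.log()
        if name == "truncate":
            return OutcomeTransform.truncate()
        raise ValueError(f"unknown transform {value!r}")
    d = dict(value)
    kind = d.pop("kind")
    level = d.pop("level", d.pop("truncation_level", 7.0))
    offset = d.pop("offset", d.pop("log_offset", 0.0))
    if d:
        raise ValueError(f"unknown transform keys {sorted(d)}")
    return OutcomeTransform(kind, truncation_level=level, log_offset=offset)


def learner_spec_from(value, seed: int, task: str = "regression") -> LearnerSpec:
    if isinstance(value, LearnerSpec):
        return value
    d = dict(value)
    return LearnerSpec(
        family=d["family"],
        task=d.get("task", task),
        hyperparameters=d.get("hyperparameters", {}),
        grid=d.get("grid"),
        cv_folds=int(d.get("cv_folds", 5)),
        seed=int(d.get("seed", seed)),
    )


@dataclass
class RunConfig:
    """Validated view over a configuration mapping."""

    raw: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def outcome_column(self) -> str:
        return self.raw.get("outcome_column", "los_days")

    def cohort_spec(self) -> CohortSpec:
        data = self.raw.get("data", {})
        syn = dict(data.get("synthetic") or {})
        syn.setdefault("seed", derive_seed(self.seed, "cohort"))
        return CohortSpec(**syn)

    def load_table(self) -> pd.DataFrame:
        data = self.raw.get("data", {})
        has_csv, has_syn = "csv" in data, "synthetic" in data
        if has_csv == has_syn:
            raise ValueError("config must name exactly one data source: data.csv or data.synthetic")
        if has_csv:
            table = pd.read_csv(data["csv"])
        else:
            table = generate_cohort(self.cohort_spec()).to_frame()
        if self.outcome_column not in table.columns:
            raise ValueError(
                f"outcome column {self.outcome_column!r} not found in data "
                f"(columns: {list(table.columns)})"
            )
        schema = self.raw.get("schema", {})
        for col in schema.get("exclude", []):
            if col in table.columns:
                table = table.drop(columns=[col])
        for col in schema.get("categorical", []):
            if col in table.columns:
                table[col] = table[col].astype(str)
        return table

    def split_spec(self) -> SplitSpec:
        d = dict(self.raw.get("split") or {})
        return SplitSpec(
            train_fraction=float(d.get("train_fraction", 2.0 / 3.0)),
            cv_folds=int(d.get("cv_folds", 5)),
            seed=int(d.get("seed", derive_seed(self.seed, "split"))),
        )

    def two_stage_config(self) -> TwoStageConfig:
        d = dict(self.raw.get("two_stage") or {})
        default_learner = {"family": "tree_ensemble"}
        return TwoStageConfig(
            classifier_spec=learner_spec_from(
                d.get("classifier", default_learner),
                derive_seed(self.seed, "classifier"),
                task="classification",
            ),
            regressor_spec=learner_spec_from(
                d.get("regressor", default_learner), derive_seed(self.seed, "regressor")
            ),
            tau_c=float(d.get("tau_c", 7.0)),
            tau_r=float(d.get("tau_r", 35.0)),
            target_short_sensitivity=float(d.get("target_short_sensitivity", 0.99)),
            stage2_transform=transform_from(d.get("stage2_transform", "log")),
            mode=d.get("mode", "short_sensitivity"),
            oof_folds=int(d.get("oof_folds", 5)),
        )

    def comparison_grid(self) -> ComparisonGrid:
        d = dict(self.raw.get("grid") or {})
        algos = [
            learner_spec_from(a, derive_seed(self.seed, "grid", str(i)))
            for i, a in enumerate(d.get("algorithms", [{"family": "tree_ensemble"}]))
        ]
        return ComparisonGrid(
            algorithms=algos,
            transforms=[transform_from(t) for t in d.get("transforms", ["identity"])],
            losses=list(d.get("losses", ["mse", "mae", "customized"])),
            approaches=list(d.get("approaches", ["one_stage"])),
        )

    def bootstrap_settings(self) -> dict:
        d = dict((self.raw.get("evaluate") or {}).get("bootstrap") or {})
        return {
            "B": int(d.get("B", 500)),
            "level": float(d.get("level", 0.95)),
            "seed": int(d.get("seed", derive_seed(self.seed, "bootstrap"))),
        }

    def sweep_taus(self) -> list[float]:
        d = dict(self.raw.get("sweep") or {})
        return [float(t) for t in d.get("taus", [7.0, 21.0, 35.0])]


def load_config(path, seed_override: int | None = None) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must contain a mapping at top level")
    seed = int(seed_override) if seed_override is not None else int(raw.get("seed", 0))
    return RunConfig(raw=raw, seed=seed)


def _config_hash(raw: dict) -> str:
    canon = json.dumps(raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(outdir, command: str, cfg: RunConfig, extra: dict | None = None) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "config": cfg.raw,
        "config_hash": _config_hash(cfg.raw),
        "seed": cfg.seed,
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
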