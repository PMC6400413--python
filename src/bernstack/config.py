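"""YAML/JSON configuration schema for models and data.

Schema::

    models:
      - {type: point, label: law, theta0: 1.0}
      - {type: interval, label: low, base_a: 1, base_b: 1, lower: 0, upper: 0.25}
      - {type: grid, label: tumor, values: [...], weights: [...]}
    prior_probs: [0.25, 0.5, 0.25]      # optional
    data:
      counts: {successes: 10, failures: 10}
      # or: sequence: [1, 0, 1, ...]

Data may also be read from a CSV file with a single 0/1 column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from bernstack.models import (
    BetaIntervalModel,
    BinaryOutcomeData,
    DiscreteGridModel,
    Model,
    PointMassModel,
)
from bernstack.bma import ModelSet

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "model_set_to_dict",
    "model_set_from_dict",
    "data_to_dict",
    "data_from_dict",
    "load_config",
    "dump_config",
    "read_outcomes_csv",
]


def model_to_dict(model: Model) -> dict:
    if isinstance(model, PointMassModel):
        return {"type": "point", "label": model.label, "theta0": model.theta0}
    if isinstance(model, BetaIntervalModel):
        return {
            "type": "interval",
            "label": model.label,
            "base_a": model.base_a,
            "base_b": model.base_b,
            "lower": model.lower,
            "upper": model.upper,
        }
    if isinstance(model, DiscreteGridModel):
        return {
            "type": "grid",
            "label": model.label,
            "values": list(model.grid_values),
            "weights": list(model.prior_weights),
        }
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def model_from_dict(d: dict) -> Model:
    kind = d.get("type")
    label = d.get("label", "")
    if kind == "point":
        return PointMassModel(theta0=float(d["theta0"]), label=label)
    if kind == "interval":
        return BetaIntervalModel(
            base_a=float(d["base_a"]),
            base_b=float(d["base_b"]),
            lower=float(d.get("lower", 0.0)),
            upper=float(d.get("upper", 1.0)),
            label=label,
        )
    if kind == "grid":
        return DiscreteGridModel(
            grid_values=[float(v) for v in d["values"]],
            prior_weights=[float(w) for w in d["weights"]],
            label=label or "grid",
        )
    raise ValueError(f"unknown model type {kind!r}; expected point|interval|grid")


def model_set_to_dict(model_set: ModelSet) -> dict:
    out = {"models": [model_to_dict(m) for m in model_set.models]}
    if model_set.prior_probs is not None:
        out["prior_probs"] = list(model_set.prior_probs)
    return out


def model_set_from_dict(d: dict) -> ModelSet:
    return ModelSet(
        [model_from_dict(m) for m in d["models"]],
        prior_probs=d.get("prior_probs"),
    )


def data_to_dict(data: BinaryOutcomeData) -> dict:
    if data.outcomes is not None:
        return {"sequence": list(data.outcomes)}
    return {"counts": {"successes": data.s, "failures": data.f}}


def data_from_dict(d: dict) -> BinaryOutcomeData:
    if "sequence" in d:
        return BinaryOutcomeData(outcomes=[int(v) for v in d["sequence"]])
    if "counts" in d:
        c = d["counts"]
        return BinaryOutcomeData(s=int(c["successes"]), f=int(c["failures"]))
    raise ValueError("data must specify 'sequence' or 'counts'")


def load_config(path) -> tuple[ModelSet, BinaryOutcomeData]:
    """Read a model-set + data config from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_set_from_dict(cfg), data_from_dict(cfg["data"])


def dump_config(model_set: ModelSet, data: BinaryOutcomeData, path=None) -> str:
    """Serialize a model set and data to YAML; optionally write to a file."""
    cfg = model_set_to_dict(model_set)
    cfg["data"] = data_to_dict(data)
    text = yaml.safe_dump(cfg, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_outcomes_csv(path, column: str | int = 0) -> BinaryOutcomeData:
    """Read an ordered 0/1 outcome column from a CSV file."""
    df = pd.read_csv(path)
    col = df.iloc[:, column] if isinstance(column, int) else df[column]
    return BinaryOutcomeData(outcomes=col.astype(int).tolist())
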