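"""Lossless YAML round-trip of hypothesis classes (the model-spec format).

Schema (one document per hypothesis class)::

    prior: [0.25, 0.25, 0.25, 0.25]
    metadata: {...}                # optional, plain scalars
    models:
    - id: V
      states: [G, X]
      rhs: {builtin: bergman_v}    # or {mass_action: [ {reactants: {A: 1},
                                   #                     products: {B: 1}}, ... ]}
      theta: {mean: [...], cov: [[...]]}
      x0: {mean: [...], cov: [[...]]}
      constants: {Gb: 92.0, Ib: 11.0}          # optional
      observations: {glucose: [1.0, 0.0]}
      forcing:                                  # optional
        insulin: {times: [...], values: [...]}

Mass-action models carry one rate parameter per reaction in ``theta``.
Raw-callable models cannot be serialized.  Unknown keys are rejected so that
typos fail loudly.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import yaml

from .models import CandidateModel, ConfigurationError, Forcing, HypothesisClass

__all__ = ["save_hypothesis_class", "load_hypothesis_class", "class_to_dict", "class_from_dict"]

_MODEL_KEYS = {"id", "states", "rhs", "theta", "x0", "constants", "observations", "forcing", "t0"}
_TOP_KEYS = {"models", "prior", "metadata"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown keys {sorted(unknown)} in {where}")


def _model_to_dict(m: CandidateModel) -> dict:
    if m.rhs_callable is not None:
        raise ConfigurationError(f"model {m.id!r} uses a raw callable rhs and cannot be serialized")
    rhs: dict[str, Any]
    if m.rhs_builtin is not None:
        rhs = {"builtin": m.rhs_builtin}
    else:
        rhs = {"mass_action": [dict(r) for r in m.reactions]}
    doc = {
        "id": m.id,
        "states": list(m.state_names),
        "rhs": rhs,
        "theta": {"mean": m.theta_mean.tolist(), "cov": m.theta_cov.tolist()},
        "x0": {"mean": m.x0_mean.tolist(), "cov": m.x0_cov.tolist()},
        "observations": {k: v.tolist() for k, v in m.observation_map.items()},
    }
    if m.constants:
        doc["constants"] = {k: float(v) for k, v in m.constants.items()}
    if m.forcing:
        doc["forcing"] = {
            k: {"times": f.times.tolist(), "values": f.values.tolist()} for k, f in m.forcing.items()
        }
    if m.t0 != 0.0:
        doc["t0"] = float(m.t0)
    return doc


def _model_from_dict(doc: dict) -> CandidateModel:
    if not isinstance(doc, dict):
        raise ConfigurationError("each model entry must be a mapping")
    _check_keys(doc, _MODEL_KEYS, f"model {doc.get('id', '?')!r}")
    for key in ("id", "states", "rhs", "theta", "x0", "observations"):
        if key not in doc:
            raise ConfigurationError(f"model entry is missing {key!r}")
    rhs = doc["rhs"]
    _check_keys(rhs, {"builtin", "mass_action"}, f"model {doc['id']!r} rhs")
    if len(rhs) != 1:
        raise ConfigurationError(f"model {doc['id']!r}: rhs needs exactly one of builtin/mass_action")
    forcing = {
        k: Forcing(np.asarray(f["times"], dtype=float), np.asarray(f["values"], dtype=float))
        for k, f in doc.get("forcing", {}).items()
    }
    return CandidateModel(
        id=str(doc["id"]),
        state_names=[str(s) for s in doc["states"]],
        x0_mean=np.asarray(doc["x0"]["mean"], dtype=float),
        x0_cov=np.asarray(doc["x0"]["cov"], dtype=float),
        theta_mean=np.asarray(doc["theta"]["mean"], dtype=float),
        theta_cov=np.asarray(doc["theta"]["cov"], dtype=float),
        observation_map={k: np.asarray(v, dtype=float) for k, v in doc["observations"].items()},
        rhs_builtin=rhs.get("builtin"),
        reactions=rhs.get("mass_action"),
        constants=dict(doc.get("constants", {})),
        forcing=forcing,
        t0=float(doc.get("t0", 0.0)),
    )


def class_to_dict(hclass: HypothesisClass) -> dict:
    doc = {
        "models": [_model_to_dict(m) for m in hclass.models],
        "prior": hclass.prior.tolist(),
    }
    if hclass.metadata:
        doc["metadata"] = dict(hclass.metadata)
    return doc


def class_from_dict(doc: dict) -> HypothesisClass:
    if not isinstance(doc, dict):
        raise ConfigurationError("model-spec document must be a mapping")
    _check_keys(doc, _TOP_KEYS, "model-spec document")
    if "models" not in doc or "prior" not in doc:
        raise ConfigurationError("model-spec needs 'models' and 'prior'")
    models = [_model_from_dict(m) for m in doc["models"]]
    return HypothesisClass(models, np.asarray(doc["prior"], dtype=float), metadata=dict(doc.get("metadata", {})))


def save_hypothesis_class(hclass: HypothesisClass, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(class_to_dict(hclass), fh, sort_keys=False)


def load_hypothesis_class(path) -> HypothesisClass:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return class_from_dict(doc)
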