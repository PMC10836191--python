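"""Reading model definitions from YAML/JSON configs and writing traces as CSV."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .markov import CohortTrace, MarkovModel, ModelValidationError, StateSpace

__all__ = ["load_config", "model_from_dict", "load_model", "trace_to_csv"]


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML (or JSON — a YAML subset) document into a dict."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ModelValidationError(f"config {path} must contain a mapping at top level")
    return data


def model_from_dict(cfg: dict[str, Any]) -> MarkovModel:
    """Build a :class:`MarkovModel` from a config mapping.

    Expected keys: ``states`` (list of labels), ``absorbing`` (list),
    ``transitions`` (list of ``{from, to, p}`` entries; omitted mass goes to
    the self-loop), ``initial`` (state -> fraction, default all mass in the
    first state), ``costs`` / ``utilities`` (state -> value, default 0 / 1 for
    non-absorbing and 0 for absorbing), ``discount_rate``, ``n_cycles`` and
    optional ``transition_costs`` (list of ``{from, to, cost}``).
    """
    names = list(cfg["states"])
    space = StateSpace(names, cfg.get("absorbing", [names[-1]]))
    s = len(space)

    mat = np.zeros((s, s))
    for entry in cfg.get("transitions", []):
        i, j = space.index(str(entry["from"])), space.index(str(entry["to"]))
        mat[i, j] = float(entry["p"])
    # remaining row mass stays put
    for i in range(s):
        off_diag = mat[i].sum() - mat[i, i]
        if mat[i, i] == 0.0:
            mat[i, i] = 1.0 - off_diag

    initial = np.zeros(s)
    init_cfg = cfg.get("initial")
    if init_cfg is None:
        initial[0] = 1.0
    else:
        for name, frac in init_cfg.items():
            initial[space.index(name)] = float(frac)

    def per_state(key: str, default: float) -> np.ndarray:
        vec = np.full(s, default)
        for idx in space.absorbing_indices:
            vec[idx] = 0.0
        for name, value in (cfg.get(key) or {}).items():
            vec[space.index(name)] = float(value)
        return vec

    transition_costs = {
        (str(e["from"]), str(e["to"])): float(e["cost"])
        for e in cfg.get("transition_costs", [])
    } or None

    return MarkovModel(
        states=space,
        transition=mat,
        initial_distribution=initial,
        n_cycles=int(cfg["n_cycles"]),
        costs=per_state("costs", 0.0),
        utilities=per_state("utilities", 1.0),
        discount_rate=float(cfg.get("discount_rate", 0.0)),
        transition_costs=transition_costs,
    )


def load_model(path: str | Path) -> MarkovModel:
    return model_from_dict(load_config(path))


def trace_to_csv(trace: CohortTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path)


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
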