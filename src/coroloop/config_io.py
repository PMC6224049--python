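"""Structured-text (YAML) round trip for models and patient specs.

The canonical form sorts keys and uses plain Python floats, so
``dump(load(text)) == text`` for canonical files and
``from_dict(to_dict(x)) == x`` for in-memory objects.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .coronary_control import CoronaryBlock
from .heart_model import ElastanceFunction, HeartChamber, Valve
from .lpn_core import Capacitor, LPNModel, VascularSegment
from .synthetic_data import ConditionTargets, NoiseSpec, SyntheticPatientSpec

__all__ = [
    "model_to_dict", "model_from_dict",
    "patient_to_dict", "patient_from_dict",
    "dump_config", "load_config",
    "write_config", "read_config",
]


def _plain(obj):
    """Recursively convert numpy scalars to plain Python types."""
    import numpy as np
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def model_to_dict(model: LPNModel) -> dict:
    if any(callable(v) for v in model.sources.values()):
        raise ValueError("callable pressure sources are not serializable")
    return _plain({
        "kind": "lpn_model",
        "chambers": [asdict(ch) for ch in model.chambers],
        "valves": [asdict(v) for v in model.valves],
        "segments": [asdict(s) for s in model.segments],
        "capacitors": [asdict(c) for c in model.capacitors],
        "coronary_blocks": [asdict(b) for b in model.coronary_blocks],
        "sources": dict(model.sources),
    })


def model_from_dict(d: dict) -> LPNModel:
    chambers = [HeartChamber(name=c["name"],
                             elastance=ElastanceFunction(**c["elastance"]),
                             volume=c["volume"], broadcast=c["broadcast"])
                for c in d["chambers"]]
    return LPNModel(
        chambers=chambers,
        valves=[Valve(**v) for v in d["valves"]],
        segments=[VascularSegment(**s) for s in d["segments"]],
        capacitors=[Capacitor(**c) for c in d.get("capacitors", [])],
        coronary_blocks=[CoronaryBlock(**b) for b in d.get("coronary_blocks", [])],
        sources=dict(d.get("sources", {})),
    )


def patient_to_dict(spec: SyntheticPatientSpec) -> dict:
    d = _plain(asdict(spec))
    d["kind"] = "synthetic_patient"
    return d


def patient_from_dict(d: dict) -> SyntheticPatientSpec:
    return SyntheticPatientSpec(
        seed=d["seed"], bsa=d["bsa"],
        rest=ConditionTargets(**d["rest"]),
        stress=ConditionTargets(**d["stress"]),
        noise=NoiseSpec(**d["noise"]),
        co_stress_ratio=d.get("co_stress_ratio", 1.45),
    )


def dump_config(obj) -> str:
    """Canonical YAML text for a model or patient spec."""
    if isinstance(obj, LPNModel):
        d = model_to_dict(obj)
    elif isinstance(obj, SyntheticPatientSpec):
        d = patient_to_dict(obj)
    elif isinstance(obj, dict):
        d = obj
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    return yaml.safe_dump(d, sort_keys=True, default_flow_style=False)


def load_config(text: str):
    d = yaml.safe_load(text)
    kind = d.get("kind")
    if kind == "lpn_model":
        return model_from_dict(d)
    if kind == "synthetic_patient":
        return patient_from_dict(d)
    raise ValueError(f"unknown config kind {kind!r}")


def write_config(obj, path: str | Path) -> None:
    Path(path).write_text(dump_config(obj))


def read_config(path: str | Path):
    return load_config(Path(path).read_text())
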