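"""Run configuration: one root seed, named substreams, full serializability."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .synth import PopulationHyperparams, StudyDesign

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, serializable to YAML/JSON.

    A run is bit-for-bit reproducible from (config, code version): every
    random draw comes from a named substream of ``seed``.
    """

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    hyperparams: PopulationHyperparams = field(default_factory=PopulationHyperparams)
    normalize_scr: bool = True
    exclude_null_responders: bool = False
    null_responder_median: float = 0.02
    robust_scr: bool = True
    n_predict_profiles: int = 200
    outdir: str = "results"

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        path.write_text(text, encoding="utf-8")


def _filter_kwargs(cls, d: Dict[str, Any]) -> Dict[str, Any]:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    # YAML round-trips tuples as lists; coerce back where needed
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        out[k] = v
    return out


def load_config(path: Optional[str] = None, **overrides: Any) -> RunConfig:
    """Load a YAML/JSON config file and apply keyword overrides."""
    data: Dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
    data.update(overrides)
    design = StudyDesign(**_filter_kwargs(StudyDesign, data.pop("design", {}) or {}))
    hyper = PopulationHyperparams(
        **_filter_kwargs(PopulationHyperparams, data.pop("hyperparams", {}) or {})
    )
    return RunConfig(design=design, hyperparams=hyper, **_filter_kwargs(RunConfig, data))
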