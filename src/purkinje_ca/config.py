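"""Run-configuration loading and validation.

A run is described by a YAML (or JSON) document with optional blocks —
``geometry``, ``transport``, ``serca``, ``ryr``, ``cpvt``, ``currents``,
``protocol``, ``numeric``, ``analysis`` — plus top-level ``seed``,
``scaled`` and output options.  Unknown keys anywhere are rejected with an
error naming the offending key; omitted keys take the package defaults, so
an empty file is a valid control-model configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .currents import _DEFAULT_BASE, IonicParams, apply_blockade, apply_isoproterenol
from .engine import Model, NumericParams, RyRParams
from .geometry import CellGeometry
from .leak import LeakParams
from .protocols import StimulusProtocol
from .transport import DiffusionParams, SercaParams

__all__ = ["RunConfig", "load_config", "build_model"]

_MODEL_KEYS = {"tau_tr", "g_sr_leak", "g_scr", "g_nsr_axial"}


@dataclass
class RunConfig:
    """Validated configuration with defaults filled in."""

    geometry: CellGeometry = field(default_factory=CellGeometry)
    transport: DiffusionParams = field(default_factory=DiffusionParams)
    serca: SercaParams = field(default_factory=SercaParams)
    ryr: RyRParams = field(default_factory=RyRParams)
    cpvt: LeakParams = field(default_factory=LeakParams)
    currents: IonicParams = field(default_factory=IonicParams)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    numeric: NumericParams = field(default_factory=NumericParams)
    model_extras: dict = field(default_factory=dict)
    isoproterenol: bool = False
    blockade: dict = field(default_factory=dict)  # channel -> fraction
    seed: int = 0
    scaled: bool = True
    out: Optional[str] = None


def _build_dataclass(cls, block: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}' block: {sorted(unknown)}")
    return cls(**block)


def _parse(doc: dict) -> RunConfig:
    doc = dict(doc or {})
    known = {
        "geometry", "transport", "serca", "ryr", "cpvt", "currents",
        "protocol", "numeric", "model", "seed", "scaled", "out",
        "isoproterenol", "blockade",
    }
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")

    cfg = RunConfig()
    cfg.geometry = _build_dataclass(CellGeometry, doc.get("geometry", {}), "geometry")
    cfg.transport = _build_dataclass(DiffusionParams, doc.get("transport", {}), "transport")
    cfg.serca = _build_dataclass(SercaParams, doc.get("serca", {}), "serca")
    cfg.ryr = _build_dataclass(RyRParams, doc.get("ryr", {}), "ryr")
    cfg.cpvt = _build_dataclass(LeakParams, doc.get("cpvt", {}), "cpvt")
    cfg.protocol = _build_dataclass(StimulusProtocol, doc.get("protocol", {}), "protocol")
    cfg.numeric = _build_dataclass(NumericParams, doc.get("numeric", {}), "numeric")

    cur = dict(doc.get("currents", {}))
    unknown = set(cur) - set(_DEFAULT_BASE)
    if unknown:
        raise ValueError(f"unknown key(s) in 'currents' block: {sorted(unknown)}")
    base = dict(_DEFAULT_BASE)
    base.update(cur)
    cfg.currents = IonicParams(base=base)

    extras = dict(doc.get("model", {}))
    unknown = set(extras) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown key(s) in 'model' block: {sorted(unknown)}")
    cfg.model_extras = extras

    cfg.isoproterenol = bool(doc.get("isoproterenol", False))
    blockade = dict(doc.get("blockade", {}))
    for chan, frac in blockade.items():
        if not (0.0 <= float(frac) <= 1.0):
            raise ValueError(f"blockade fraction for {chan} must lie in [0, 1]")
    cfg.blockade = blockade
    cfg.seed = int(doc.get("seed", 0))
    cfg.scaled = bool(doc.get("scaled", True))
    cfg.out = doc.get("out")
    return cfg


def load_config(path: str) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("configuration root must be a mapping")
    return _parse(doc)


def build_model(cfg: RunConfig) -> Model:
    """Assemble the simulation :class:`Model`, applying modifier stacks."""
    ionic = cfg.currents
    if cfg.isoproterenol:
        ionic = apply_isoproterenol(ionic)
    for chan, frac in cfg.blockade.items():
        ionic = apply_blockade(ionic, chan, float(frac))
    return Model(
        geometry=cfg.geometry,
        ionic=ionic,
        serca=cfg.serca,
        diffusion=cfg.transport,
        ryr=cfg.ryr,
        leak=cfg.cpvt,
        numeric=cfg.numeric,
        **cfg.model_extras,
    )
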