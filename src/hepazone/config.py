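"""YAML/JSON experiment configuration.

Recognized keys (all optional, with the canonical channel as default)::

    channel.length_cm     channel.diameter_cm
    bc.inlet1_uM          bc.inlet2_uM
    solute.mw             reference.mw          reference.D_cm2_s
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .diffusion import (
    CHIR99021,
    RHODAMINE_B_AGAROSE,
    BoundaryConditions,
    ChannelGeometry,
    ReferenceDiffusion,
    SoluteDescriptor,
)

__all__ = ["ExperimentConfig", "load_config"]


class ExperimentConfig:
    """Parsed channel/experiment configuration."""

    def __init__(self, raw: "dict | None" = None):
        raw = raw or {}
        ch = raw.get("channel", {})
        bc = raw.get("bc", {})
        sol = raw.get("solute", {})
        ref = raw.get("reference", {})
        self.geometry = ChannelGeometry(
            ch.get("length_cm", 9.0),
            ch.get("diameter_cm", 0.5),
            ch.get("n_grid", 901),
        )
        self.boundary_conditions = BoundaryConditions(
            bc.get("inlet1_uM", 0.0), bc.get("inlet2_uM", 9.0)
        )
        self.solute = SoluteDescriptor(
            sol.get("name", CHIR99021.name), sol.get("mw", CHIR99021.molecular_weight)
        )
        ref_solute = SoluteDescriptor(
            ref.get("name", RHODAMINE_B_AGAROSE.solute.name),
            ref.get("mw", RHODAMINE_B_AGAROSE.solute.molecular_weight),
        )
        self.reference = ReferenceDiffusion(
            ref_solute,
            ref.get("D_cm2_s", RHODAMINE_B_AGAROSE.D),
            ref.get("medium", RHODAMINE_B_AGAROSE.medium),
        )


def load_config(path: "str | Path | None") -> ExperimentConfig:
    if path is None:
        return ExperimentConfig()
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ExperimentConfig(raw)
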