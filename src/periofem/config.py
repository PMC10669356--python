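"""YAML run configuration.

A run file looks like::

    tooth:
      tooth_class: single_rooted
      root_length: 13.0
    reduction_mm: [0, 1, 2, 3]      # scalar or list
    load:
      n_steps: 70
      axial_N: 70.0
      transverse_N: 35.0
      calibrate_to_MPa: 0.48        # optional pressure anchor
    mesh:
      size: 0.85
      order: 2
    support: outer_bone_boundary
    failure_threshold_MPa: 0.9
    materials:                      # optional overrides
      pdl: {elastic_modulus: 68.9, poisson_ratio: 0.45}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .geometry import ToothParams
from .materials import MaterialSpec
from .solver import LoadProtocol

__all__ = ["load_config", "tooth_from_config", "protocol_from_config",
           "materials_from_config"]


def load_config(path) -> dict:
    with open(Path(path)) as fh:
        return yaml.safe_load(fh) or {}


def tooth_from_config(cfg: dict) -> ToothParams:
    block = dict(cfg.get("tooth", {}))
    cls = block.pop("tooth_class", "single_rooted")
    if "bone_block_dims" in block:
        block["bone_block_dims"] = tuple(block["bone_block_dims"])
    factory = ToothParams.multi if cls == "multi_rooted" else ToothParams.single
    return factory(**block)


def protocol_from_config(cfg: dict) -> LoadProtocol:
    block = cfg.get("load", {})
    return LoadProtocol(
        n_steps=int(block.get("n_steps", 70)),
        terminal_force=(float(block.get("axial_N", 70.0)),
                        float(block.get("transverse_N", 35.0))))


def materials_from_config(cfg: dict) -> dict[str, MaterialSpec] | None:
    block = cfg.get("materials")
    if not block:
        return None
    return {name: MaterialSpec(name, float(v["elastic_modulus"]),
                               float(v["poisson_ratio"]))
            for name, v in block.items()}
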