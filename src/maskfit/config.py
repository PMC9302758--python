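"""YAML configuration for material, solver, contact and sweep settings.

Recognized keys (all optional, shown with defaults):

.. code-block:: yaml

    material:
      E_MPa: 0.03
      nu: 0.49
      h_mm: 2.0
      kappa: 0.8333333333
      drilling_factor: 1.0e-6
    solver:
      rel_tol: 1.0e-8
    contact:
      push_depth_mm: 3.0
      direction: [0.0, 0.0, -1.0]
      max_active_set_iters: 50
      tol: 1.0e-10
    sweep:
      adjustable_point_indices: [0, 1, 2, 3]
      axis: X
      n_steps: 5
      step_magnitude_mm: 3.0
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .contact_solver import DEFAULT_DIRECTION
from .shell_fem import ShellMaterial

__all__ = ["ContactSettings", "SweepSettings", "load_config", "material_from_config"]


@dataclass(frozen=True)
class ContactSettings:
    push_depth_mm: float = 3.0
    direction: tuple = DEFAULT_DIRECTION
    max_active_set_iters: int = 50
    tol: float = 1e-10


@dataclass(frozen=True)
class SweepSettings:
    adjustable_point_indices: tuple = (0, 1, 2, 3)
    axis: str = "X"
    n_steps: int = 5
    step_magnitude_mm: float = 3.0


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def material_from_config(cfg: dict) -> ShellMaterial:
    m = cfg.get("material", {})
    return ShellMaterial(
        E=float(m.get("E_MPa", 0.03)),
        nu=float(m.get("nu", 0.49)),
        h=float(m.get("h_mm", 2.0)),
        kappa=float(m.get("kappa", 5.0 / 6.0)),
        drilling_factor=float(m.get("drilling_factor", 1e-6)),
    )


def contact_from_config(cfg: dict) -> ContactSettings:
    c = cfg.get("contact", {})
    return ContactSettings(
        push_depth_mm=float(c.get("push_depth_mm", 3.0)),
        direction=tuple(c.get("direction", DEFAULT_DIRECTION)),
        max_active_set_iters=int(c.get("max_active_set_iters", 50)),
        tol=float(c.get("tol", 1e-10)),
    )


def sweep_from_config(cfg: dict) -> SweepSettings:
    s = cfg.get("sweep", {})
    return SweepSettings(
        adjustable_point_indices=tuple(s.get("adjustable_point_indices", (0, 1, 2, 3))),
        axis=str(s.get("axis", "X")),
        n_steps=int(s.get("n_steps", 5)),
        step_magnitude_mm=float(s.get("step_magnitude_mm", 3.0)),
    )
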