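"""Nodal contact pressures from Lagrange multipliers via tributary areas.

Each contact node's pressure is its contact force divided by its tributary
area, one third of the summed areas of the triangles incident to the
vertex — so the tributary areas of all vertices tile the surface exactly.
Summary statistics (mean, max, SD with the population divisor) are reported
over all paired nodes *including* zero-pressure ones, because uncontacted
patches are part of fit quality; an excluding-zeros variant is kept for
sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_solver import ContactProblem, ContactSolution
from .errors import GeometryError, ParameterError
from .mesh_core import TriSurfaceMesh, save_vtk

__all__ = [
    "PressureField",
    "tributary_area",
    "tributary_areas",
    "pressures_from_solution",
    "export_pressure_csv",
    "export_pressure_vtk",
]


def tributary_areas(mesh: TriSurfaceMesh) -> np.ndarray:
    """Tributary area (mm^2) of every vertex: sum of incident areas / 3."""
    areas = mesh.triangle_areas()
    out = np.zeros(mesh.n_vertices)
    for c in range(3):
        np.add.at(out, mesh.triangles[:, c], areas / 3.0)
    return out


def tributary_area(mesh: TriSurfaceMesh, vertex: int) -> float:
    """Tributary area of one vertex; isolated vertices are an error."""
    if not 0 <= vertex < mesh.n_vertices:
        raise ParameterError(f"vertex {vertex} out of range")
    incident = np.any(mesh.triangles == vertex, axis=1)
    if not np.any(incident):
        raise GeometryError(f"vertex {vertex} has no incident triangles (zero area)")
    return float(mesh.triangle_areas()[incident].sum() / 3.0)


@dataclass
class PressureField:
    """Nodal contact pressures over the paired face vertices (MPa)."""

    vertices: np.ndarray        # all paired face vertices (incl. zero pressure)
    pressures: np.ndarray       # MPa, aligned with `vertices`
    areas: np.ndarray           # tributary areas (mm^2), aligned
    forces: np.ndarray          # nodal contact force lambda (N), aligned
    mean: float
    max: float
    sd: float
    zero_pressure_count: int
    mean_excl_zeros: float
    sd_excl_zeros: float

    @property
    def total_force(self) -> float:
        return float(self.forces.sum())

    def as_vertex_field(self, n_vertices: int) -> np.ndarray:
        """Dense per-vertex pressure field (zeros off the contact set)."""
        field = np.zeros(n_vertices)
        field[self.vertices] = self.pressures
        return field


def pressures_from_solution(
    mesh: TriSurfaceMesh,
    solution: ContactSolution,
    problem: ContactProblem,
) -> PressureField:
    """Convert per-pair contact forces into nodal pressures.

    Active pairs get lambda / A; pairs dropped in gap screening or released
    by the active-set loop get pressure 0 and are counted in
    ``zero_pressure_count``.  Summary statistics use all paired nodes.
    """
    all_vertices = np.asarray(problem.all_face_vertices)
    forces = np.zeros(len(all_vertices))
    active_vertices = problem.face_vertices[solution.active_pairs]
    lookup = {int(v): i for i, v in enumerate(all_vertices)}
    for v, lam in zip(active_vertices, solution.lambdas):
        forces[lookup[int(v)]] = lam

    areas = tributary_areas(mesh)[all_vertices]
    if np.any(areas <= 0):
        raise GeometryError("paired vertex with nonpositive tributary area")
    pressures = forces / areas

    nonzero = pressures > 0
    n = len(pressures)
    mean = float(pressures.mean()) if n else 0.0
    sd = float(pressures.std()) if n else 0.0  # population divisor
    mx = float(pressures.max()) if n else 0.0
    mean_nz = float(pressures[nonzero].mean()) if np.any(nonzero) else 0.0
    sd_nz = float(pressures[nonzero].std()) if np.any(nonzero) else 0.0
    return PressureField(
        vertices=all_vertices,
        pressures=pressures,
        areas=areas,
        forces=forces,
        mean=mean,
        max=mx,
        sd=sd,
        zero_pressure_count=int(n - nonzero.sum()),
        mean_excl_zeros=mean_nz,
        sd_excl_zeros=sd_nz,
    )


def export_pressure_csv(mesh: TriSurfaceMesh, field: PressureField, path) -> None:
    import pandas as pd

    xyz = mesh.vertices[field.vertices]
    pd.DataFrame(
        {
            "vertex_id": field.vertices,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "area_mm2": field.areas,
            "lambda_N": field.forces,
            "pressure_MPa": field.pressures,
        }
    ).to_csv(path, index=False)


def export_pressure_vtk(mesh: TriSurfaceMesh, field: PressureField, path) -> None:
    save_vtk(
        mesh,
        path,
        point_data={"contact_pressure_MPa": field.as_vertex_field(mesh.n_vertices)},
    )
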