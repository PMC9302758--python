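"""Enumeration, evaluation and ranking of mask design candidates.

A sweep adjusts chosen reference points of a base design over a symmetric
grid of offsets along one axis (default: five X-steps of 3 mm, i.e.
{-6, -3, 0, +3, +6} per point), evaluates every candidate's contact
pressure on a face model condensed *once* to a master set covering all
candidates, and ranks designs.  The fit criterion follows "lower mean and
lower SD of contact pressure is better", scalarized as the sum of z-scores
of the two statistics across candidates (equal weights, scale-free).
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .condensation import ReducedModel
from .contact_solver import DEFAULT_DIRECTION, build_contact_problem, solve_contact
from .errors import CoverageError, ParameterError
from .mask_geometry import MaskDesign, adjust_reference_points, sample_mask_nodes
from .mesh_core import TriSurfaceMesh
from .pressure_metrics import pressures_from_solution
from .shell_fem import FaceFEModel

__all__ = ["SweepSpec", "SweepResult", "enumerate_candidates", "run_sweep", "rank_candidates"]

CANDIDATE_CAP = 10**6


@dataclass(frozen=True)
class SweepSpec:
    """Grid sweep over reference-point offsets.

    n_steps odd: offsets are {-k m, ..., 0, ..., +k m} with k = (n_steps-1)/2
    and m = step_magnitude; candidate count = n_steps ** n_adjustable.
    """

    base_design: MaskDesign
    adjustable_point_indices: tuple[int, ...]
    axis: str = "X"
    n_steps: int = 5
    step_magnitude: float = 3.0
    push_depth: float = 3.0
    direction: tuple[float, float, float] = DEFAULT_DIRECTION

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.n_steps % 2 == 0:
            raise ParameterError("n_steps must be an odd integer >= 1")
        if not self.adjustable_point_indices:
            raise ParameterError("need at least one adjustable point")
        if self.push_depth <= 0:
            raise ParameterError("push_depth must be positive")

    @property
    def offsets(self) -> np.ndarray:
        k = (self.n_steps - 1) // 2
        return self.step_magnitude * np.arange(-k, k + 1, dtype=float)

    @property
    def n_candidates(self) -> int:
        return self.n_steps ** len(self.adjustable_point_indices)


def enumerate_candidates(spec: SweepSpec) -> list[MaskDesign]:
    """All candidate designs on the full Cartesian offset grid.

    Ordering is lexicographic in the per-point offsets (first adjustable
    point varies slowest); candidate ids encode the offsets.
    """
    if spec.n_candidates > CANDIDATE_CAP:
        raise ParameterError(
            f"candidate count {spec.n_candidates} exceeds cap {CANDIDATE_CAP}"
        )
    designs = []
    for combo in itertools.product(spec.offsets, repeat=len(spec.adjustable_point_indices)):
        d = spec.base_design
        for idx, off in zip(spec.adjustable_point_indices, combo):
            if off != 0.0:
                d = adjust_reference_points(d, [idx], spec.axis, off)
        label = ",".join(f"{o:+g}" for o in combo)
        d = MaskDesign(d.reference_points, d.profile, d.spacing, design_id=f"[{label}]")
        designs.append(d)
    return designs


@dataclass
class SweepResult:
    """Per-candidate pressure summaries plus the best/worst ranking."""

    records: pd.DataFrame
    best_id: str
    worst_id: str
    offsets: list[tuple[float, ...]] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.records)

    def summary(self) -> dict:
        return {
            "n_candidates": int(self.n_candidates),
            "best_id": self.best_id,
            "worst_id": self.worst_id,
            "mean_pressure_range": [
                float(self.records["mean_MPa"].min()),
                float(self.records["mean_MPa"].max()),
            ],
        }


def rank_candidates(records: pd.DataFrame) -> tuple[str, str]:
    """Best/worst candidate ids by the z-score fit criterion.

    score = z(mean pressure) + z(pressure SD), z with the population SD
    across candidates (a statistic with zero spread contributes 0); lowest
    score is best.  Ties break by lower mean, then lexicographic id.
    """
    if len(records) == 0:
        raise ParameterError("need at least one candidate record")

    def z(col: np.ndarray) -> np.ndarray:
        s = col.std()  # population divisor (ddof=0)
        return (col - col.mean()) / s if s > 0 else np.zeros_like(col)

    score = z(records["mean_MPa"].to_numpy()) + z(records["sd_MPa"].to_numpy())
    means = records["mean_MPa"].to_numpy()
    # final tie-break: enumeration (lexicographic-offset) order = row order
    keys = [(score[i], means[i], i) for i in range(len(records))]
    best = min(range(len(keys)), key=lambda i: keys[i])
    worst = max(range(len(keys)), key=lambda i: keys[i])
    return str(records["design_id"].iloc[best]), str(records["design_id"].iloc[worst])


def _check_coverage(
    mesh: TriSurfaceMesh, reduced: ReducedModel, design: MaskDesign, nodes
) -> None:
    """A candidate's mask nodes must pair to master vertices even when the
    nearest *free* vertex is consulted; otherwise the condensation master
    set does not cover this candidate."""
    free_mask = np.ones(mesh.n_vertices, dtype=bool)
    free_mask[mesh.boundary_vertices] = False
    free_vertices = np.flatnonzero(free_mask)
    tree = cKDTree(mesh.vertices[free_vertices])
    _, idx = tree.query(nodes.nodes)
    nearest_free = free_vertices[idx]
    uncovered = ~np.isin(nearest_free, reduced.master_nodes)
    if np.any(uncovered):
        raise CoverageError(
            f"candidate {design.design_id}: {int(uncovered.sum())} mask nodes "
            "pair to non-master face vertices; re-select master nodes over "
            "all sweep candidates"
        )


def run_sweep(
    model: FaceFEModel,
    reduced: ReducedModel,
    spec: SweepSpec,
    check_coverage: bool = True,
) -> SweepResult:
    """Evaluate every candidate on the shared condensed model and rank.

    The reduced stiffness is factored once and reused; per-candidate work is
    mask sampling, pairing, the saddle-point contact solve and the pressure
    summary.  Raises :class:`CoverageError` if any candidate touches face
    vertices outside the master set.
    """
    mesh = model.mesh
    candidates = enumerate_candidates(spec)
    offsets = list(itertools.product(spec.offsets, repeat=len(spec.adjustable_point_indices)))
    rows = []
    for design, offs in zip(candidates, offsets):
        t0 = time.perf_counter()
        nodes = sample_mask_nodes(design)
        if check_coverage:
            _check_coverage(mesh, reduced, design, nodes)
        problem = build_contact_problem(
            mesh, reduced, nodes, spec.push_depth, spec.direction
        )
        solution = solve_contact(reduced, problem)
        pressure = pressures_from_solution(mesh, solution, problem)
        rows.append(
            {
                "design_id": design.design_id,
                "offsets": offs,
                "mean_MPa": pressure.mean,
                "sd_MPa": pressure.sd,
                "max_MPa": pressure.max,
                "zero_pressure_count": pressure.zero_pressure_count,
                "total_force_N": pressure.total_force,
                "solve_time_s": time.perf_counter() - t0,
            }
        )
    records = pd.DataFrame(rows)
    best, worst = rank_candidates(records)
    return SweepResult(records=records, best_id=best, worst_id=worst, offsets=offsets)
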