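"""Parameter-plane region maps, viability screening, and phase-plane dynamics.

A region map classifies every cell of a 2-D parameter grid by the ESS
status of Bequeath and Stay (``B_only`` / ``S_only`` / ``both_ESS`` /
``neither_ESS``), with nonviable cells — where a monomorphic Stay
population cannot persist even in expectation — overriding the
classification.

The phase plane tracks the joint discrete-time dynamics of the Bequeath
frequency ``p`` and the residency rate ``R``.  The residency update is one
application of the residency recurrence; the frequency update is the
discrete replicator rule

    p' = p W(B) / (p W(B) + (1 - p) W(S))

with both inclusive-fitness values evaluated at the current state.  An
interior equilibrium is a root of the selection differential
``W(B) - W(S)`` along the residency isocline ``R = R_ss(p)``; where a
``neither_ESS`` regime holds, the differential changes sign from positive
at ``p = 0`` to negative at ``p = 1`` and a stable mixture exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ModelParams
from .global_dispersal import (
    TIE_TOL,
    classify_ess,
    fitness_components,
    selection_differential,
    steady_state_R,
    winner_class_probs,
    _residency_map,
)
from .local_dispersal import classify_ess_local

__all__ = [
    "viability",
    "viability_margin",
    "RegionGrid",
    "scan_plane",
    "PhasePoint",
    "phase_step",
    "find_interior_equilibrium",
]

#: Parameter names accepted as scan axes.
AXIS_NAMES = ("rho", "log2_C_A", "s_A", "s_J", "d_A", "d_J")


def viability_margin(params: ModelParams, strategy: str) -> float:
    """Expected net replacement margin of a monomorphic population.

    For Stay the household keeps the adult home (survival ``s_A``) and
    sends the juvenile out (``d_J s_J``); for Bequeath the roles swap.  The
    population persists in expectation iff the margin is positive.  This is
    an expectation-level condition: populations barely above zero remain at
    high demographic risk.
    """
    if strategy == "S":
        return params.s_A + params.d_J * params.s_J - 1.0
    if strategy == "B":
        return params.s_J + params.d_A * params.s_A - 1.0
    raise ValueError(f"strategy must be 'B' or 'S', got {strategy!r}")


def viability(params: ModelParams, strategy: str) -> bool:
    """Whether a monomorphic population of the given strategy is viable."""
    return viability_margin(params, strategy) > 0.0


@dataclass
class RegionGrid:
    """Classification of a 2-D parameter plane, one layer per dispersal mode."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    fixed: ModelParams
    cells: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: axis1, axis2, mode, classification."""
        rows = []
        for mode, grid in self.cells.items():
            for i, v1 in enumerate(self.axis1_values):
                for j, v2 in enumerate(self.axis2_values):
                    rows.append(
                        {
                            self.axis1_name: v1,
                            self.axis2_name: v2,
                            "mode": mode,
                            "classification": grid[i, j],
                        }
                    )
        return pd.DataFrame(rows)

    def region_mask(self, mode: str, label: str) -> np.ndarray:
        """Boolean mask of cells carrying the given classification."""
        return self.cells[mode] == label


def _apply_axis(params: ModelParams, name: str, value: float) -> ModelParams:
    if name == "log2_C_A":
        return params.with_(C_A=float(2.0**value))
    if name not in AXIS_NAMES:
        raise ValueError(f"unknown axis name {name!r}; expected one of {AXIS_NAMES}")
    return params.with_(**{name: float(value)})


def scan_plane(
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    fixed: ModelParams,
    modes: Iterable[str] = ("global",),
) -> RegionGrid:
    """Classify every cell of a 2-D parameter plane.

    ``axis1`` and ``axis2`` are ``(name, values)`` pairs; names come from
    ``rho``, ``log2_C_A``, ``s_A``, ``s_J``, ``d_A``, ``d_J``.  Each cell
    is classified independently under the requested dispersal modes
    (``"global"`` and/or ``"local"``); the computation is deterministic.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    vals1 = np.asarray(vals1, dtype=float)
    vals2 = np.asarray(vals2, dtype=float)
    if vals1.size < 2 or vals2.size < 2:
        raise ValueError("each axis needs at least 2 grid values")
    modes = tuple(modes)
    for m in modes:
        if m not in ("global", "local"):
            raise ValueError(f"unknown dispersal mode {m!r}")

    grid = RegionGrid(
        axis1_name=name1,
        axis1_values=vals1,
        axis2_name=name2,
        axis2_values=vals2,
        fixed=fixed,
    )
    classifiers = {"global": classify_ess, "local": classify_ess_local}
    for mode in modes:
        cells = np.empty((vals1.size, vals2.size), dtype=object)
        for i, v1 in enumerate(vals1):
            for j, v2 in enumerate(vals2):
                params = _apply_axis(_apply_axis(fixed, name1, v1), name2, v2)
                cells[i, j] = classifiers[mode](params)
        grid.cells[mode] = cells
    return grid


@dataclass(frozen=True)
class PhasePoint:
    """One state of the joint (p, R) dynamics, with the last step's deltas."""

    p: float
    R_t: float
    delta_p: float = 0.0
    delta_R: float = 0.0
    frozen: bool = False


def phase_step(point: PhasePoint, params: ModelParams) -> PhasePoint:
    """Advance the joint (p, R) dynamics by one generation.

    The residency rate takes one step of its recurrence at the current
    frequency; the frequency takes one discrete-replicator step using the
    inclusive-fitness values at the current state.  Boundary frequencies
    are absorbing.  If total fitness vanishes the state is returned frozen.
    """
    p, R = point.p, point.R_t
    params_p = params.with_(p=p)
    R_next = min(max(_residency_map(params_p, R, winner_class_probs(params_p, R)), 0.0), 1.0)
    fc = fitness_components(params_p, R)
    total = p * fc.W_B + (1.0 - p) * fc.W_S
    if total <= 0.0:
        return PhasePoint(p=p, R_t=R_next, delta_p=0.0, delta_R=R_next - R, frozen=True)
    p_next = p * fc.W_B / total
    return PhasePoint(
        p=p_next, R_t=R_next, delta_p=p_next - p, delta_R=R_next - R
    )


def iterate_phase(
    point: PhasePoint,
    params: ModelParams,
    generations: int,
) -> list[PhasePoint]:
    """Iterate :func:`phase_step`, returning the full trajectory."""
    traj = [point]
    for _ in range(generations):
        point = phase_step(point, params)
        traj.append(point)
    return traj


def _boundary_differential(params: ModelParams, p: float) -> float:
    return selection_differential(params.with_(p=p))


def find_interior_equilibrium(
    params: ModelParams,
    p_grid: int = 41,
    p_tol: float = 1e-6,
    eps: float = 1e-4,
) -> list[tuple[float, float]]:
    """Locate interior equilibria of the frequency dynamics.

    Scans the selection differential ``W(B) - W(S)`` along the residency
    isocline ``R = R_ss(p)`` on a grid over ``p`` in ``[eps, 1 - eps]`` and
    bisects every sign change to ``p_tol``.  Returns the (possibly empty)
    sorted list of ``(p*, R*)`` pairs.

    Raises ``ValueError`` for the degenerate neutral plane (the
    differential is within tie tolerance of zero across the whole grid,
    e.g. ``C_A = 1, rho = 1``), where every frequency is an equilibrium.
    """
    from scipy.optimize import bisect

    ps = np.linspace(eps, 1.0 - eps, p_grid)
    g = np.array([_boundary_differential(params, p) for p in ps])
    if np.all(np.abs(g) < TIE_TOL):
        raise ValueError(
            "degenerate neutral parameter point: every frequency is an equilibrium"
        )
    roots: list[tuple[float, float]] = []
    for k in range(len(ps) - 1):
        a, b, ga, gb = ps[k], ps[k + 1], g[k], g[k + 1]
        if ga == 0.0:
            roots.append(float(a))
            continue
        if ga * gb < 0:
            roots.append(
                float(
                    bisect(
                        lambda p: _boundary_differential(params, p),
                        a,
                        b,
                        xtol=p_tol,
                    )
                )
            )
    out = []
    for p_star in sorted(set(round(r, 9) for r in roots)):
        R_star = steady_state_R(params.with_(p=p_star)).R
        out.append((p_star, R_star))
    return out
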