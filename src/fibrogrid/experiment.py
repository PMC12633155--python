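"""Brush masks, scenario presets and region summary statistics.

A brush mask selects the cells that receive user-set input concentrations;
everything outside the mask stays at the default (zero) stimulus.  Three
preset scenarios cover the canonical showcase runs:

* case 1 — no brush, all inputs zero: the grid relaxes from its noisy start.
* case 2 — X-shaped brush, TGFB held at 1 inside the mask.
* case 3 — X-shaped brush, six pro-fibrotic inputs (TGFB, AngII, IL6, IL1,
  TNFa, NE) held at 1, probing pathway synergy.

All presets run 500 iterations at a fixed 0.1 time step with snapshots at
iterations 0, 100, 300 and 500.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ContractError, SchemaError
from .grid import GridState
from .network import NetworkSpec

CASE3_INPUTS = ("TGFB", "AngII", "IL6", "IL1", "TNFa", "NE")
PRESET_DURATION = 500
PRESET_SNAPSHOTS = (0, 100, 300, 500)
PRESET_DT = 0.1


@dataclass
class BrushMask:
    """Boolean cell-selection plane."""

    selected: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 2 or (
            self.selected.shape[0] != self.selected.shape[1]
        ):
            raise ContractError("mask must be a square boolean plane")

    @property
    def grid_size(self) -> int:
        return self.selected.shape[0]

    @property
    def count(self) -> int:
        return int(self.selected.sum())


def make_brush_mask(shape: str, params: dict, N: int) -> BrushMask:
    """Build a mask of the given shape on an N x N grid.

    Shapes: ``rect`` (row, col, height, width), ``disk`` (row, col, radius,
    Euclidean inclusion), ``x_shape`` (both full diagonals, optionally
    thickened by ``width``), ``cells`` (an explicit freehand cell list).
    """
    if N < 3:
        raise ContractError("grid size must be >= 3")
    sel = np.zeros((N, N), dtype=bool)
    params = dict(params or {})
    if shape == "rect":
        r, c = int(params.get("row", 0)), int(params.get("col", 0))
        h, w = int(params.get("height", 1)), int(params.get("width", 1))
        if h < 1 or w < 1:
            raise ContractError("rect height/width must be >= 1")
        if not (0 <= r and r + h <= N and 0 <= c and c + w <= N):
            raise ContractError("rect extends outside the grid")
        sel[r:r + h, c:c + w] = True
    elif shape == "disk":
        r0, c0 = float(params.get("row", N // 2)), float(params.get("col", N // 2))
        radius = float(params.get("radius", 1.0))
        ii, jj = np.mgrid[0:N, 0:N]
        sel[(ii - r0) ** 2 + (jj - c0) ** 2 <= radius ** 2] = True
    elif shape == "x_shape":
        width = int(params.get("width", 1))
        if width < 1:
            raise ContractError("x_shape width must be >= 1")
        idx = np.arange(N)
        for off in range(-(width - 1), width):
            sel[idx, (idx + off) % N] = True
            sel[idx, (N - 1 - idx + off) % N] = True
        if width == 1:
            # exact diagonals, no wrap-around thickening
            sel[:] = False
            sel[idx, idx] = True
            sel[idx, N - 1 - idx] = True
    elif shape == "cells":
        for cell in params.get("cells", ()):
            i, j = int(cell[0]), int(cell[1])
            if not (0 <= i < N and 0 <= j < N):
                raise ContractError(
                    f"cell ({i}, {j}) outside a {N}x{N} grid"
                )
            sel[i, j] = True
    else:
        raise ContractError(f"unknown brush shape {shape!r}")
    return BrushMask(sel)


@dataclass
class Scenario:
    """Spatial stimulation protocol: who gets stimulated, with what, for how
    long.  Assigned input concentrations are held constant for the whole
    run; unassigned inputs are zero everywhere."""

    mask: BrushMask
    assignments: dict[str, float] = field(default_factory=dict)
    default_input: float = 0.0
    duration_iterations: int = PRESET_DURATION
    snapshot_iterations: tuple[int, ...] = PRESET_SNAPSHOTS
    probe_cells: tuple[tuple[int, int], ...] = ()
    fixed_dt: float | None = PRESET_DT
    name: str = "custom"

    def __post_init__(self) -> None:
        self.snapshot_iterations = tuple(int(i) for i in self.snapshot_iterations)
        self.probe_cells = tuple(tuple(int(x) for x in c) for c in self.probe_cells)
        for mol, value in self.assignments.items():
            if not (0.0 <= value <= 1.0):
                raise ContractError(
                    f"assignment {mol}={value} outside [0, 1]"
                )
        if not (0.0 <= self.default_input <= 1.0):
            raise ContractError("default_input outside [0, 1]")
        if len(self.probe_cells) > 2:
            raise ContractError("at most 2 probe cells may be selected")
        for it in self.snapshot_iterations:
            if not (0 <= it <= self.duration_iterations):
                raise ContractError(
                    f"snapshot iteration {it} outside "
                    f"[0, {self.duration_iterations}]"
                )
        if self.fixed_dt is not None and self.fixed_dt <= 0:
            raise ContractError("fixed_dt must be positive")


def apply_inputs(
    scenario: Scenario, spec: NetworkSpec, N: int | None = None
) -> np.ndarray:
    """Per-cell external input field shaped (row, col, input species):
    the assigned value inside the mask, the default outside, zero for
    unassigned inputs everywhere."""
    if N is None:
        N = scenario.mask.grid_size
    if scenario.mask.grid_size != N:
        raise ContractError(
            f"mask is {scenario.mask.grid_size}x{scenario.mask.grid_size}, "
            f"grid is {N}x{N}"
        )
    unknown = set(scenario.assignments) - set(spec.inputs)
    if unknown:
        raise ContractError(
            f"assignment(s) to non-input species: {sorted(unknown)}"
        )
    field_arr = np.zeros((N, N, len(spec.inputs)))
    sel = scenario.mask.selected
    for k, name in enumerate(spec.inputs):
        if name in scenario.assignments:
            plane = np.full((N, N), scenario.default_input)
            plane[sel] = scenario.assignments[name]
            field_arr[:, :, k] = plane
    return field_arr


def scenario_case(case_id: int, N: int) -> Scenario:
    """The three preset scenarios (pure function of case id and grid size)."""
    if case_id not in (1, 2, 3):
        raise ContractError(f"case_id must be 1, 2 or 3, got {case_id!r}")
    probe = ((N // 2, N // 2), (N // 2, (N // 2 + N // 4) % N))
    if case_id == 1:
        mask = BrushMask(np.zeros((N, N), dtype=bool))
        assignments: dict[str, float] = {}
    else:
        mask = make_brush_mask("x_shape", {}, N)
        if case_id == 2:
            assignments = {"TGFB": 1.0}
        else:
            assignments = {name: 1.0 for name in CASE3_INPUTS}
    return Scenario(
        mask=mask,
        assignments=assignments,
        duration_iterations=PRESET_DURATION,
        snapshot_iterations=PRESET_SNAPSHOTS,
        probe_cells=probe,
        fixed_dt=PRESET_DT,
        name=f"case{case_id:02d}",
    )


def ring_mask(mask: BrushMask) -> np.ndarray:
    """Cells not in the mask with at least one masked 8-neighbor (with
    periodic wrap, matching the diffusion neighborhood)."""
    sel = mask.selected
    dilated = sel.copy()
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if (di, dj) != (0, 0):
                dilated |= np.roll(sel, (di, dj), axis=(0, 1))
    return dilated & ~sel


@dataclass
class RegionSummary:
    """Arithmetic means of one field over the mask partition.

    ``mean_inside`` is NaN for an empty mask.  ``mean_outside`` covers every
    unmasked cell; ``mean_far`` excludes the mask-adjacent ring from it.
    """

    field: str
    mean_inside: float
    mean_outside: float
    mean_ring: float
    mean_far: float
    min: float
    max: float


def region_summary(
    state: GridState, mask: BrushMask, field_name: str
) -> RegionSummary:
    """Summary statistics of a named plane over inside/outside/ring regions."""
    plane = state.field_plane(field_name)
    if mask.grid_size != plane.shape[0]:
        raise ContractError("mask and state grid sizes differ")
    sel = mask.selected
    ring = ring_mask(mask)
    outside = ~sel
    far = outside & ~ring

    def mean_of(region: np.ndarray) -> float:
        return float(plane[region].mean()) if region.any() else float("nan")

    return RegionSummary(
        field=field_name,
        mean_inside=mean_of(sel),
        mean_outside=mean_of(outside),
        mean_ring=mean_of(ring),
        mean_far=mean_of(far),
        min=float(plane.min()),
        max=float(plane.max()),
    )


# -----------------------------------------------------------------------------
# scenario files
# -----------------------------------------------------------------------------

def scenario_to_dict(scenario: Scenario, mask_spec: dict | None = None) -> dict:
    """Serializable scenario document.  ``mask_spec`` (shape + params)
    round-trips compactly; otherwise the explicit cell list is stored."""
    if mask_spec is None:
        cells = [[int(i), int(j)] for i, j in np.argwhere(scenario.mask.selected)]
        mask_spec = {"shape": "cells", "params": {"cells": cells}}
    return {
        "name": scenario.name,
        "grid_size": scenario.mask.grid_size,
        "mask": mask_spec,
        "assignments": dict(scenario.assignments),
        "default_input": scenario.default_input,
        "duration_iterations": scenario.duration_iterations,
        "snapshot_iterations": list(scenario.snapshot_iterations),
        "probe_cells": [list(c) for c in scenario.probe_cells],
        "fixed_dt": scenario.fixed_dt,
    }


def scenario_from_dict(doc: dict, N: int | None = None) -> Scenario:
    if N is None:
        N = int(doc.get("grid_size", 100))
    mask_doc = doc.get("mask", {"shape": "cells", "params": {"cells": []}})
    try:
        mask = make_brush_mask(
            mask_doc["shape"], mask_doc.get("params", {}), N
        )
    except KeyError as exc:
        raise SchemaError(f"scenario mask missing key {exc}") from exc
    return Scenario(
        mask=mask,
        assignments={
            str(k): float(v) for k, v in (doc.get("assignments") or {}).items()
        },
        default_input=float(doc.get("default_input", 0.0)),
        duration_iterations=int(doc.get("duration_iterations", PRESET_DURATION)),
        snapshot_iterations=tuple(
            doc.get("snapshot_iterations", PRESET_SNAPSHOTS)
        ),
        probe_cells=tuple(tuple(c) for c in doc.get("probe_cells", ())),
        fixed_dt=doc.get("fixed_dt", PRESET_DT),
        name=str(doc.get("name", "custom")),
    )


def load_scenario(path: str | Path, N: int | None = None) -> Scenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError("scenario file must be a mapping at top level")
    return scenario_from_dict(doc, N)


def save_scenario(
    scenario: Scenario, path: str | Path, mask_spec: dict | None = None
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            scenario_to_dict(scenario, mask_spec), fh, sort_keys=False
        )
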