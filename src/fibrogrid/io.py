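"""Result writers: heatmap PNGs, CSV matrices, probe time series, manifests.

Outputs are designed for bit-exact reproducibility: floats are written with
17 significant digits (repr round-trip), PNGs carry no timestamps, and the
run manifest records everything needed to regenerate the outputs (network
content hash, scenario, configuration, seed, software version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import __version__
from .errors import ContractError
from .grid import Trajectory

FLOAT_FMT = "%.17g"


def render_heatmap(
    plane: np.ndarray, path: str | Path, scale: int = 1
) -> Path:
    """Write a PNG of a concentration plane on a fixed black-to-yellow scale.

    The scale is always [0, 1] — never per-frame autoscaled — so frames from
    different iterations are visually comparable.  Luminance increases
    monotonically with concentration (black at 0, saturated yellow at 1).
    """
    plane = np.asarray(plane, dtype=float)
    if not np.isfinite(plane).all():
        raise ContractError("heatmap plane contains non-finite values")
    if plane.min() < -1e-12 or plane.max() > 1 + 1e-12:
        raise ContractError("heatmap plane values must lie in [0, 1]")
    v = np.clip(np.round(plane * 255.0), 0, 255).astype(np.uint8)
    rgb = np.stack([v, v, np.zeros_like(v)], axis=-1)
    img = Image.fromarray(rgb, mode="RGB")
    if scale > 1:
        img = img.resize(
            (img.width * scale, img.height * scale), Image.NEAREST
        )
    path = Path(path)
    img.save(path, format="PNG")
    return path


def write_plane_csv(plane: np.ndarray, path: str | Path) -> Path:
    """One field plane as a CSV matrix, full float precision."""
    path = Path(path)
    np.savetxt(path, np.asarray(plane, dtype=float), fmt=FLOAT_FMT,
               delimiter=",")
    return path


def read_plane_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def _probe_column(trajectory: Trajectory, series, mol: str) -> np.ndarray:
    """Resolve a molecule name against a probe series: ECM fields first,
    then feedback fields, then intracellular species (same precedence as
    :meth:`GridState.field_plane`)."""
    if mol in trajectory.ecm_names:
        return series.ecm[:, trajectory.ecm_names.index(mol)]
    if mol in trajectory.feedback_names:
        return series.feedback[:, trajectory.feedback_names.index(mol)]
    if mol in trajectory.species_names:
        return series.intracellular[:, trajectory.species_names.index(mol)]
    raise ContractError(f"unknown molecule {mol!r}")


def write_probes_csv(
    trajectory: Trajectory, molecules: list[str], path: str | Path
) -> Path:
    """Probe-cell time series: iteration, time, one column per selected
    molecule per probed cell (column ``MOL_r<i>c<j>``)."""
    path = Path(path)
    cells = sorted(trajectory.probes)
    columns = ["iteration", "time"]
    data: list[np.ndarray] = []
    if cells:
        first = trajectory.probes[cells[0]]
        data = [first.iterations.astype(float), first.times]
    for cell in cells:
        series = trajectory.probes[cell]
        i, j = cell
        for mol in molecules:
            columns.append(f"{mol}_r{i}c{j}")
            data.append(_probe_column(trajectory, series, mol))
    with open(path, "w") as fh:
        fh.write(",".join(columns) + "\n")
        if data:
            rows = np.column_stack(data)
            np.savetxt(fh, rows, fmt=FLOAT_FMT, delimiter=",")
    return path


def write_snapshot_container(
    trajectory: Trajectory, fields: list[str], path: str | Path
) -> Path:
    """All requested snapshot planes in one compressed array container."""
    arrays = {}
    for it, state in sorted(trajectory.snapshots.items()):
        for name in fields:
            arrays[f"{name}_iter{it:04d}"] = state.field_plane(name)
    np.savez_compressed(Path(path), **arrays)
    return Path(path)


def file_sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs bit for bit."""

    network_path: str
    network_sha256: str
    scenario: dict
    grid_size: int
    rates: dict
    step_policy: dict
    seed: int
    initial_noise_amplitude: float
    version: str = __version__
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path


def load_manifest(path: str | Path) -> RunManifest:
    doc = json.loads(Path(path).read_text())
    return RunManifest(**doc)
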