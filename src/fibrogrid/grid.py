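"""Spatial state and the clamped forward-Euler integrator.

The tissue is an N x N grid of identical cells with periodic boundaries.
Each cell runs the intracellular network of :mod:`fibrogrid.network`; cells
are coupled through diffusible feedback fields and slowly diffusing ECM
fields.  Diffusion uses the discrete 8-neighborhood operator

    dC_ij/dt  +=  D * sum_{(m,n) in N_ij} (C_mn - C_ij)

summed over all eight neighbors with no distance weighting; the modulo rule
on indices wraps the grid edges.  One step performs a single forward-Euler
update of everything and then clamps every concentration to [0, 1].  The
time step is either fixed or chosen adaptively as

    dt = min(dt_max, theta / max|dX/dt|)

so no variable moves by more than ``theta`` per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .errors import ContractError, IntegrationError
from .network import (
    ECM_DIFFUSION_FACTOR,
    NetworkSpec,
    RateConstants,
    evaluate_derivatives,
)

_OFFSETS = tuple(
    (di, dj)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    if (di, dj) != (0, 0)
)


@dataclass
class StepPolicy:
    """Adaptive step control: never exceed ``dt_max`` and never let any
    variable change by more than ``safety_theta`` in one step."""

    dt_max: float = 0.1
    safety_theta: float = 0.1

    def __post_init__(self) -> None:
        if self.dt_max <= 0:
            raise ContractError("dt_max must be positive")
        if self.safety_theta <= 0:
            raise ContractError("safety_theta must be positive")


@dataclass
class SimulationConfig:
    """Grid size, rate constants, step policy, seed and initial noise.

    ``rates=None`` uses the constants declared by the network file; a
    non-None value overrides them (the CLI's ``--set`` mechanism).
    """

    grid_size: int = 100
    rates: RateConstants | None = None
    step: StepPolicy = dc_field(default_factory=StepPolicy)
    seed: int = 0
    initial_noise_amplitude: float = 0.1

    def __post_init__(self) -> None:
        if self.grid_size < 3:
            raise ContractError(
                "grid_size must be >= 3 for a well-defined 8-neighborhood"
            )
        if not (0.0 <= self.initial_noise_amplitude <= 1.0):
            raise ContractError("initial_noise_amplitude must be in [0, 1]")


@dataclass
class GridState:
    """Complete spatial state at one instant.

    ``intracellular`` is indexed (row, col, species); ``feedback`` and
    ``ecm`` are stacks of planes indexed (field, row, col).  After any
    completed step every stored concentration lies in [0, 1].
    """

    intracellular: np.ndarray
    feedback: np.ndarray
    ecm: np.ndarray
    time: float = 0.0
    iteration: int = 0
    species_names: tuple[str, ...] = ()
    feedback_names: tuple[str, ...] = ()
    ecm_names: tuple[str, ...] = ()

    @property
    def grid_size(self) -> int:
        return self.intracellular.shape[0]

    def copy(self) -> "GridState":
        return GridState(
            intracellular=self.intracellular.copy(),
            feedback=self.feedback.copy(),
            ecm=self.ecm.copy(),
            time=self.time,
            iteration=self.iteration,
            species_names=self.species_names,
            feedback_names=self.feedback_names,
            ecm_names=self.ecm_names,
        )

    def field_plane(self, name: str) -> np.ndarray:
        """Look up a named plane: ECM fields first, then feedback fields,
        then intracellular species."""
        if name in self.ecm_names:
            return self.ecm[self.ecm_names.index(name)]
        if name in self.feedback_names:
            return self.feedback[self.feedback_names.index(name)]
        if name in self.species_names:
            return self.intracellular[:, :, self.species_names.index(name)]
        raise ContractError(f"unknown field or species {name!r}")


def neighbor_coords(i: int, j: int, N: int) -> list[tuple[int, int]]:
    """The eight neighbors of (i, j), wrapped periodically modulo N."""
    if N < 3:
        raise ContractError("grid size must be >= 3")
    if not (0 <= i < N and 0 <= j < N):
        raise ContractError(f"cell ({i}, {j}) outside a {N}x{N} grid")
    return [((i + di) % N, (j + dj) % N) for di, dj in _OFFSETS]


def _neighbor_sum(plane: np.ndarray) -> np.ndarray:
    total = np.zeros_like(plane)
    for di, dj in _OFFSETS:
        total += np.roll(plane, (di, dj), axis=(0, 1))
    return total


def diffusion_term(plane: np.ndarray, D: float) -> np.ndarray:
    """D * sum over the 8-neighborhood of (neighbor - self), per cell.

    Antisymmetry of the pairwise differences makes the returned plane sum to
    zero over the grid: the operator conserves mass.
    """
    plane = np.asarray(plane, dtype=float)
    return D * (_neighbor_sum(plane) - 8.0 * plane)


def adaptive_dt(max_abs_rate: float, policy: StepPolicy) -> float:
    """min(dt_max, theta / max|rate|); the cap when nothing is changing."""
    if max_abs_rate < 0:
        raise ContractError("max_abs_rate must be >= 0")
    if max_abs_rate == 0.0:
        return policy.dt_max
    return min(policy.dt_max, policy.safety_theta / max_abs_rate)


def count_state_variables(spec: NetworkSpec, N: int) -> int:
    """Number of coupled ODE state variables on an N x N grid: one per
    species per cell plus one per feedback field per cell."""
    return (len(spec.species) + len(spec.feedback_fields)) * N * N


def _raise_nonfinite(
    deriv: np.ndarray, names: Sequence[str], kind: str
) -> None:
    bad = np.argwhere(~np.isfinite(deriv))
    if kind == "intracellular":
        i, j, s = bad[0]
        where = f"cell ({i}, {j}), species {names[s]!r}"
    else:
        k, i, j = bad[0]
        where = f"cell ({i}, {j}), {kind} field {names[k]!r}"
    raise IntegrationError(f"non-finite derivative at {where}")


def step(
    state: GridState,
    spec: NetworkSpec,
    config: SimulationConfig,
    inputs: np.ndarray,
    dt: float | None = None,
) -> GridState:
    """One clamped forward-Euler update of the whole grid.

    ``inputs`` is the external stimulus field shaped (row, col, input
    species).  When ``dt`` is None the step size is chosen adaptively from
    the maximum absolute derivative across every state variable.
    """
    N = config.grid_size
    comp = spec.compiled()
    if state.intracellular.shape != (N, N, comp.n_species):
        raise ContractError(
            f"intracellular state shaped {state.intracellular.shape}, "
            f"expected {(N, N, comp.n_species)}"
        )
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape != (N, N, len(spec.inputs)):
        raise ContractError(
            f"inputs shaped {inputs.shape}, expected "
            f"{(N, N, len(spec.inputs))}"
        )
    rates = config.rates if config.rates is not None else spec.rates

    fb_local = np.moveaxis(state.feedback, 0, -1) if len(
        spec.feedback_fields
    ) else np.zeros((N, N, 0))
    d_intra = evaluate_derivatives(
        state.intracellular, inputs, fb_local, spec, rates
    )

    d_fb = np.zeros_like(state.feedback)
    for k, f in enumerate(spec.feedback_fields):
        D = f.diffusion if f.diffusion is not None else rates.k_diffusion
        lam = f.clearance if f.clearance is not None else rates.k_degradation
        d_fb[k] = (
            diffusion_term(state.feedback[k], D)
            + rates.k_production * state.intracellular[:, :, comp.fb_precursor[k]]
            - lam * state.feedback[k]
        )

    d_ecm = np.zeros_like(state.ecm)
    D_ecm = ECM_DIFFUSION_FACTOR * rates.k_diffusion
    for m in range(len(spec.ecm_fields)):
        d_ecm[m] = (
            rates.k_production
            * state.intracellular[:, :, comp.ecm_precursor[m]]
            - rates.k_degradation * state.ecm[m]
            + diffusion_term(state.ecm[m], D_ecm)
        )

    if not np.isfinite(d_intra).all():
        _raise_nonfinite(d_intra, state.species_names or spec.species_names(),
                         "intracellular")
    if d_fb.size and not np.isfinite(d_fb).all():
        _raise_nonfinite(d_fb, [f.name for f in spec.feedback_fields],
                         "feedback")
    if d_ecm.size and not np.isfinite(d_ecm).all():
        _raise_nonfinite(d_ecm, [f.name for f in spec.ecm_fields], "ecm")

    if dt is None:
        max_rate = float(abs(d_intra).max(initial=0.0))
        if d_fb.size:
            max_rate = max(max_rate, float(abs(d_fb).max()))
        if d_ecm.size:
            max_rate = max(max_rate, float(abs(d_ecm).max()))
        dt = adaptive_dt(max_rate, config.step)
    elif dt <= 0:
        raise ContractError("dt must be positive")

    return GridState(
        intracellular=np.clip(state.intracellular + dt * d_intra, 0.0, 1.0),
        feedback=np.clip(state.feedback + dt * d_fb, 0.0, 1.0),
        ecm=np.clip(state.ecm + dt * d_ecm, 0.0, 1.0),
        time=state.time + dt,
        iteration=state.iteration + 1,
        species_names=state.species_names,
        feedback_names=state.feedback_names,
        ecm_names=state.ecm_names,
    )


@dataclass
class ProbeSeries:
    """Per-iteration record of one probed cell."""

    cell: tuple[int, int]
    iterations: np.ndarray
    times: np.ndarray
    intracellular: np.ndarray  # (T+1, S)
    feedback: np.ndarray       # (T+1, K)
    ecm: np.ndarray            # (T+1, M)


@dataclass
class Trajectory:
    """Snapshots at requested iterations plus probe-cell time series."""

    snapshots: dict[int, GridState]
    probes: dict[tuple[int, int], ProbeSeries]
    times: np.ndarray
    seed: int
    species_names: tuple[str, ...] = ()
    feedback_names: tuple[str, ...] = ()
    ecm_names: tuple[str, ...] = ()


def initial_state(
    spec: NetworkSpec, config: SimulationConfig, rng: np.random.Generator
) -> GridState:
    """Seeded initial condition: every intracellular species and every ECM
    plane starts at independent uniform noise on [0, amplitude] (or the
    species' declared ``initial_range``); secreted feedback pools start
    empty."""
    N = config.grid_size
    S = len(spec.species)
    amp = config.initial_noise_amplitude
    intra = rng.random((N, N, S))
    lo = np.zeros(S)
    hi = np.full(S, amp)
    for s_idx, s in enumerate(spec.species):
        if s.initial_range is not None:
            lo[s_idx], hi[s_idx] = s.initial_range
    intra = lo + (hi - lo) * intra
    ecm = amp * rng.random((len(spec.ecm_fields), N, N))
    fb = np.zeros((len(spec.feedback_fields), N, N))
    return GridState(
        intracellular=intra,
        feedback=fb,
        ecm=ecm,
        time=0.0,
        iteration=0,
        species_names=spec.species_names(),
        feedback_names=tuple(f.name for f in spec.feedback_fields),
        ecm_names=tuple(f.name for f in spec.ecm_fields),
    )


def run(
    scenario,
    spec: NetworkSpec,
    config: SimulationConfig,
) -> Trajectory:
    """Simulate a scenario: seeded noisy start, constant brush-assigned
    inputs, ``duration_iterations`` Euler steps, snapshots at the requested
    iterations.  Deterministic given (scenario, spec, config, seed)."""
    from .experiment import apply_inputs  # local import to avoid a cycle

    duration = scenario.duration_iterations
    snap_at = sorted(set(scenario.snapshot_iterations))
    if snap_at and (snap_at[0] < 0 or snap_at[-1] > duration):
        raise ContractError(
            f"snapshot iterations {snap_at} outside [0, {duration}]"
        )
    rng = np.random.default_rng(config.seed)
    state = initial_state(spec, config, rng)
    inputs = apply_inputs(scenario, spec, config.grid_size)

    probes = list(scenario.probe_cells or ())
    probe_rows = {tuple(c): [] for c in probes}
    times = [state.time]
    snapshots: dict[int, GridState] = {}

    def record(st: GridState) -> None:
        if st.iteration in snap_at:
            snapshots[st.iteration] = st.copy()
        for cell in probe_rows:
            i, j = cell
            probe_rows[cell].append((
                st.iteration, st.time,
                st.intracellular[i, j].copy(),
                st.feedback[:, i, j].copy() if st.feedback.size else
                np.zeros(len(spec.feedback_fields)),
                st.ecm[:, i, j].copy() if st.ecm.size else
                np.zeros(len(spec.ecm_fields)),
            ))

    record(state)
    for _ in range(duration):
        state = step(state, spec, config, inputs, dt=scenario.fixed_dt)
        times.append(state.time)
        record(state)

    probe_series = {}
    for cell, rows in probe_rows.items():
        probe_series[cell] = ProbeSeries(
            cell=cell,
            iterations=np.array([r[0] for r in rows]),
            times=np.array([r[1] for r in rows]),
            intracellular=np.array([r[2] for r in rows]),
            feedback=np.array([r[3] for r in rows]),
            ecm=np.array([r[4] for r in rows]),
        )
    return Trajectory(
        snapshots=snapshots,
        probes=probe_series,
        times=np.array(times),
        seed=config.seed,
        species_names=spec.species_names(),
        feedback_names=tuple(f.name for f in spec.feedback_fields),
        ecm_names=tuple(f.name for f in spec.ecm_fields),
    )
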