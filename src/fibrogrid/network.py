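"""Per-cell signaling network: species, regulatory edges, rate constants.

Every cell of the spatial grid runs the same ordinary-differential-equation
network over normalized activity levels in [0, 1].  Three kinetic motifs are
distinguished by the species' role:

* **input species** integrate an external stimulus and the local diffusible
  feedback concentration::

      dX/dt = k_input * I_external + k_feedback * C_feedback - k_degradation * X

* **all other species** follow multiplicative mass-action-style kinetics: a
  sum of production terms (one per production edge; the edge's activators are
  multiplied together, which realizes AND gates), minus inhibition terms
  proportional to the species' own level times the inhibitor product, minus
  first-order degradation::

      dX/dt =  sum_j  k_j * prod(activators_j)
             - sum_l  k_l * X * prod(inhibitors_l)
             - k_degradation * X

Receptor activation (ligand * total receptor pool, with the pool normalized
to 1) and kinase activation (upstream kinase * substrate, opposed by a
phosphatase) are special cases of the same edge algebra; receptors get the
faster ``k_receptor`` default on their ligand edges.

Unless an edge carries an explicit ``rate_override``, its rate constant is
chosen by class: ``k_receptor`` for production edges targeting a receptor
species, ``k_activation`` for every other production edge, and
``k_inhibition`` for inhibition edges.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ContractError, SchemaError

MODULES = frozenset({
    "input", "receptor", "second_messenger", "kinase_phosphatase", "mapk",
    "transcription_factor", "mechanotransduction", "ecm_precursor",
    "feedback_precursor", "other",
})

#: External-to-intracellular slow-down of matrix diffusion: secreted ECM
#: proteins spread at 20% of the feedback-molecule rate.
ECM_DIFFUSION_FACTOR = 0.2


@dataclass(frozen=True)
class Species:
    """One molecular state variable of the per-cell network."""

    name: str
    module: str = "other"
    is_input: bool = False
    initial_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise SchemaError(
                f"species {self.name!r}: unknown module {self.module!r}"
            )
        if self.initial_range is not None:
            lo, hi = self.initial_range
            if not (0.0 <= lo <= hi <= 1.0):
                raise SchemaError(
                    f"species {self.name!r}: initial_range {self.initial_range} "
                    "must satisfy 0 <= lo <= hi <= 1"
                )


@dataclass(frozen=True)
class RegulatoryEdge:
    """A production or inhibition term acting on ``target``.

    ``activators`` are multiplied together (an AND gate when there are
    several).  For ``sign == "inhibition"`` the listed species act as
    inhibitors: the term is proportional to the target's own level times the
    product of the inhibitors.
    """

    target: str
    activators: tuple[str, ...]
    sign: str = "production"
    rate_override: float | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "activators", tuple(self.activators))
        if self.sign not in ("production", "inhibition"):
            raise SchemaError(
                f"edge -> {self.target!r}: sign must be 'production' or "
                f"'inhibition', got {self.sign!r}"
            )
        if not self.activators:
            kind = "activator" if self.sign == "production" else "inhibitor"
            raise SchemaError(
                f"edge -> {self.target!r}: needs at least one {kind} species"
            )
        if self.rate_override is not None and self.rate_override <= 0:
            raise SchemaError(
                f"edge -> {self.target!r}: rate_override must be positive, "
                f"got {self.rate_override}"
            )


@dataclass(frozen=True)
class RateConstants:
    """The eight global rate constants exposed to the user.

    Defaults follow the normalized kinetics the reference model was tuned
    for; all are strictly positive.
    """

    k_input: float = 1.0
    k_feedback: float = 0.5
    k_degradation: float = 1.0
    k_receptor: float = 2.0
    k_inhibition: float = 0.5
    k_activation: float = 1.0
    k_production: float = 0.01
    k_diffusion: float = 0.25

    def __post_init__(self) -> None:
        for name in self.names():
            if getattr(self, name) <= 0:
                raise SchemaError(f"rate constant {name} must be positive")

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.names()}

    def replace(self, **overrides: float) -> "RateConstants":
        unknown = set(overrides) - set(self.names())
        if unknown:
            raise SchemaError(
                f"unknown rate constant(s) {sorted(unknown)}; valid names are "
                f"{', '.join(self.names())}"
            )
        return dataclasses.replace(self, **overrides)


@dataclass(frozen=True)
class FeedbackField:
    """A diffusible paracrine/autocrine field produced from an intracellular
    precursor, cleared at rate ``clearance`` and fed back into the input
    species named by ``feeds``.

    ``diffusion``/``clearance`` of ``None`` fall back to the global
    ``k_diffusion``/``k_degradation`` constants, keeping the slider semantics
    of the eight tunable rates.
    """

    name: str
    precursor: str
    feeds: str | None = None
    diffusion: float | None = None
    clearance: float | None = None

    def __post_init__(self) -> None:
        if self.diffusion is not None and self.diffusion < 0:
            raise SchemaError(f"feedback field {self.name!r}: diffusion < 0")
        if self.clearance is not None and self.clearance < 0:
            raise SchemaError(f"feedback field {self.name!r}: clearance < 0")


@dataclass(frozen=True)
class EcmField:
    """An extracellular matrix field secreted from its intracellular
    precursor; ECM fields diffuse at ``ECM_DIFFUSION_FACTOR`` times the
    feedback rate."""

    name: str
    precursor: str


class _Compiled:
    """Index-resolved view of a NetworkSpec for fast evaluation."""

    __slots__ = (
        "n_species", "index", "input_index", "feeds_pairs", "edge_target",
        "edge_acts", "edge_sign", "edge_class", "edge_override",
        "fb_precursor", "ecm_precursor",
    )

    def __init__(self, spec: "NetworkSpec") -> None:
        self.index = {s.name: i for i, s in enumerate(spec.species)}
        self.n_species = len(spec.species)
        self.input_index = np.array(
            [self.index[n] for n in spec.inputs], dtype=np.intp
        )
        # (feedback field position, index of the input species it feeds)
        self.feeds_pairs = [
            (k, self.index[f.feeds])
            for k, f in enumerate(spec.feedback_fields)
            if f.feeds is not None
        ]
        module = {s.name: s.module for s in spec.species}
        self.edge_target = []
        self.edge_acts = []
        self.edge_sign = []
        self.edge_class = []
        self.edge_override = []
        for e in spec.edges:
            self.edge_target.append(self.index[e.target])
            self.edge_acts.append([self.index[a] for a in e.activators])
            self.edge_sign.append(e.sign)
            if e.sign == "inhibition":
                klass = "k_inhibition"
            elif module[e.target] == "receptor":
                klass = "k_receptor"
            else:
                klass = "k_activation"
            self.edge_class.append(klass)
            self.edge_override.append(e.rate_override)
        self.fb_precursor = np.array(
            [self.index[f.precursor] for f in spec.feedback_fields],
            dtype=np.intp,
        )
        self.ecm_precursor = np.array(
            [self.index[f.precursor] for f in spec.ecm_fields], dtype=np.intp
        )

    def edge_rates(self, rates: RateConstants) -> np.ndarray:
        out = np.empty(len(self.edge_target))
        for i, (klass, override) in enumerate(
            zip(self.edge_class, self.edge_override)
        ):
            out[i] = override if override is not None else getattr(rates, klass)
        return out


@dataclass
class NetworkSpec:
    """A validated per-cell network plus its diffusible field declarations."""

    species: list[Species]
    edges: list[RegulatoryEdge]
    inputs: list[str]
    feedback_fields: list[FeedbackField] = field(default_factory=list)
    ecm_fields: list[EcmField] = field(default_factory=list)
    rates: RateConstants = field(default_factory=RateConstants)
    name: str = "unnamed"

    def __post_init__(self) -> None:
        self.validate()
        self._compiled: _Compiled | None = None

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.species]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate species name(s): {sorted(dupes)}")
        known = set(names)
        for e in self.edges:
            for ref in (e.target, *e.activators):
                if ref not in known:
                    raise SchemaError(
                        f"edge -> {e.target!r} (activators "
                        f"{list(e.activators)}) references unknown species "
                        f"{ref!r}"
                    )
        input_modules = {
            s.name for s in self.species if s.module == "input" or s.is_input
        }
        if set(self.inputs) != input_modules:
            raise SchemaError(
                "inputs list must match the species flagged as inputs: "
                f"inputs={sorted(self.inputs)} vs "
                f"flagged={sorted(input_modules)}"
            )
        for e in self.edges:
            if e.target in set(self.inputs):
                raise SchemaError(
                    f"edge targets input species {e.target!r}; input species "
                    "are driven only by external stimulus and feedback"
                )
        for f in self.feedback_fields:
            if f.precursor not in known:
                raise SchemaError(
                    f"feedback field {f.name!r}: unknown precursor "
                    f"{f.precursor!r}"
                )
            if f.feeds is not None and f.feeds not in set(self.inputs):
                raise SchemaError(
                    f"feedback field {f.name!r}: feeds {f.feeds!r} which is "
                    "not an input species"
                )
        for f in self.ecm_fields:
            if f.precursor not in known:
                raise SchemaError(
                    f"ecm field {f.name!r}: unknown precursor {f.precursor!r}"
                )

    # -- introspection --------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def index_of(self, name: str) -> int:
        return self.compiled().index[name]

    def module_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for s in self.species:
            census[s.module] = census.get(s.module, 0) + 1
        return census

    def reachable_from_inputs(self) -> set[str]:
        """Species reachable from any input along directed production edges."""
        adjacency: dict[str, set[str]] = {}
        for e in self.edges:
            if e.sign == "production":
                for a in e.activators:
                    adjacency.setdefault(a, set()).add(e.target)
        seen = set(self.inputs)
        stack = list(self.inputs)
        while stack:
            node = stack.pop()
            for nxt in adjacency.get(node, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    def compiled(self) -> _Compiled:
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled


# -----------------------------------------------------------------------------
# derivative evaluation
# -----------------------------------------------------------------------------

def _coerce(values, names: Sequence[str], what: str, like: np.ndarray) -> np.ndarray:
    """Accept an array aligned with ``names`` or a name->value mapping."""
    if isinstance(values, Mapping):
        unknown = set(values) - set(names)
        if unknown:
            raise ContractError(f"unknown {what} name(s): {sorted(unknown)}")
        arr = np.zeros(like.shape[:-1] + (len(names),))
        for i, n in enumerate(names):
            arr[..., i] = values.get(n, 0.0)
        return arr
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1:] != (len(names),):
        raise ContractError(
            f"{what} vector has trailing dimension {arr.shape[-1] if arr.ndim else 0}, "
            f"expected {len(names)}"
        )
    return arr


def evaluate_derivatives(
    state: np.ndarray,
    external_inputs,
    feedback_local,
    spec: NetworkSpec,
    rates: RateConstants | None = None,
) -> np.ndarray:
    """Time derivative of every intracellular species.

    ``state`` has the species axis last and may carry leading grid axes, so
    the same code serves a single cell ``(S,)`` and a whole grid ``(N, N, S)``.
    ``external_inputs`` aligns with ``spec.inputs`` and ``feedback_local``
    with ``spec.feedback_fields`` (arrays or name->value mappings).
    Pure function of its arguments.
    """
    rates = rates if rates is not None else spec.rates
    comp = spec.compiled()
    state = np.asarray(state, dtype=float)
    if state.shape[-1:] != (comp.n_species,):
        raise ContractError(
            f"state vector has trailing dimension "
            f"{state.shape[-1] if state.ndim else 0}, expected "
            f"{comp.n_species} species"
        )
    ext = _coerce(external_inputs, spec.inputs, "input", state)
    fb_names = [f.name for f in spec.feedback_fields]
    fb = _coerce(feedback_local, fb_names, "feedback field", state)

    deriv = -rates.k_degradation * state
    if comp.input_index.size:
        deriv[..., comp.input_index] += rates.k_input * ext
    for field_pos, input_idx in comp.feeds_pairs:
        deriv[..., input_idx] += rates.k_feedback * fb[..., field_pos]

    edge_rates = comp.edge_rates(rates)
    for rate, target, acts, sign in zip(
        edge_rates, comp.edge_target, comp.edge_acts, comp.edge_sign
    ):
        term = rate * state[..., acts[0]]
        for a in acts[1:]:
            term = term * state[..., a]
        if sign == "production":
            deriv[..., target] += term
        else:
            deriv[..., target] -= term * state[..., target]
    return deriv


def cell_derivatives(
    state: np.ndarray,
    external_inputs,
    feedback_local,
    spec: NetworkSpec,
    rates: RateConstants | None = None,
) -> np.ndarray:
    """Derivative vector of a single cell (see :func:`evaluate_derivatives`)."""
    state = np.asarray(state, dtype=float)
    if state.ndim != 1:
        raise ContractError("cell_derivatives expects a 1-D state vector")
    return evaluate_derivatives(state, external_inputs, feedback_local, spec, rates)


# -----------------------------------------------------------------------------
# file I/O
# -----------------------------------------------------------------------------

def _parse_range(raw) -> tuple[float, float] | None:
    if raw is None:
        return None
    lo, hi = raw
    return (float(lo), float(hi))


def network_from_dict(doc: dict, name: str = "unnamed") -> NetworkSpec:
    """Build and validate a NetworkSpec from a parsed network document."""
    if not isinstance(doc, dict):
        raise SchemaError("network file must be a mapping at top level")
    try:
        raw_species = doc["species"]
        raw_edges = doc["edges"]
    except KeyError as exc:
        raise SchemaError(f"network file missing required key {exc}") from exc
    inputs = list(doc.get("inputs", []))
    species = []
    for item in raw_species:
        if isinstance(item, str):
            item = {"name": item}
        species.append(Species(
            name=item["name"],
            module=item.get("module", "other"),
            is_input=bool(item.get("is_input", item.get("module") == "input")),
            initial_range=_parse_range(item.get("initial_range")),
        ))
    edges = []
    for item in raw_edges:
        edges.append(RegulatoryEdge(
            target=item["target"],
            activators=tuple(item.get("activators", item.get("inhibitors", ()))),
            sign=item.get("sign", "production"),
            rate_override=item.get("rate_override"),
            note=item.get("note"),
        ))
    if not inputs:
        inputs = [s.name for s in species if s.module == "input" or s.is_input]
    feedback_fields = [
        FeedbackField(
            name=item["name"],
            precursor=item["precursor"],
            feeds=item.get("feeds"),
            diffusion=item.get("diffusion"),
            clearance=item.get("clearance"),
        )
        for item in doc.get("feedback_fields", [])
    ]
    ecm_fields = [
        EcmField(name=item["name"], precursor=item["precursor"])
        for item in doc.get("ecm_fields", [])
    ]
    rates = RateConstants(**doc.get("rates", {}))
    return NetworkSpec(
        species=species,
        edges=edges,
        inputs=inputs,
        feedback_fields=feedback_fields,
        ecm_fields=ecm_fields,
        rates=rates,
        name=doc.get("name", name),
    )


def load_network(path: str | Path) -> NetworkSpec:
    """Load and validate a network specification file (YAML or JSON)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return network_from_dict(doc, name=path.stem)


def network_to_dict(spec: NetworkSpec) -> dict:
    doc = {
        "name": spec.name,
        "species": [
            {
                "name": s.name,
                "module": s.module,
                **(
                    {"initial_range": list(s.initial_range)}
                    if s.initial_range is not None else {}
                ),
            }
            for s in spec.species
        ],
        "edges": [
            {
                "target": e.target,
                "activators": list(e.activators),
                "sign": e.sign,
                **({"rate_override": e.rate_override}
                   if e.rate_override is not None else {}),
                **({"note": e.note} if e.note else {}),
            }
            for e in spec.edges
        ],
        "inputs": list(spec.inputs),
        "feedback_fields": [
            {
                "name": f.name, "precursor": f.precursor,
                **({"feeds": f.feeds} if f.feeds else {}),
                **({"diffusion": f.diffusion} if f.diffusion is not None else {}),
                **({"clearance": f.clearance} if f.clearance is not None else {}),
            }
            for f in spec.feedback_fields
        ],
        "ecm_fields": [
            {"name": f.name, "precursor": f.precursor} for f in spec.ecm_fields
        ],
        "rates": spec.rates.as_dict(),
    }
    return doc


def save_network(spec: NetworkSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(spec), fh, sort_keys=False)
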