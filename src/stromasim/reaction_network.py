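"""Biochemical reaction networks with mass-action and saturating kinetics.

A :class:`ReactionNetwork` is a list of species, a list of reactions with
structured rate laws, and a parameter table.  It compiles to an ODE
right-hand side ``f(t, x, u)`` where ``x`` collects the dynamical species
(internal and secreted) and ``u`` the external-input species whose values
are imposed from outside the cell (e.g. ligand levels at the cell surface).

Three rate-law kinds cover every reaction used by the cell models:

``mass_action``
    ``k * prod_i x_i**order_i`` — association, dissociation, production and
    degradation steps.
``saturating``
    ``k * (prod modifiers) * x_s / (x_s + K)`` — enzymatic steps such as
    receptor-complex-driven phosphorylation, saturating in the substrate.
``constant_source``
    ``k`` — zero-order supply (only used when constitutive production is
    switched on).

Networks serialize losslessly to YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "SpeciesSpec",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "ValidationReport",
    "NetworkDefinitionError",
    "SolverError",
    "evaluate_rate",
    "assemble_rhs",
    "simulate_network",
    "check_network",
    "save_network",
    "load_network",
]

SPECIES_ROLES = ("internal", "secreted-signal", "external-input")
RATE_KINDS = ("mass_action", "saturating", "constant_source")

#: magnitude below which trajectory values are floored to exactly zero
ZERO_FLOOR = 1e-12


class NetworkDefinitionError(ValueError):
    """A rate law or reaction references an undefined symbol."""


class SolverError(RuntimeError):
    """The integrator produced a non-finite state."""

    def __init__(self, message: str, last_good_time: float | None = None):
        super().__init__(message)
        self.last_good_time = last_good_time


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species.

    ``role`` distinguishes internal species, secreted signals (dynamical,
    but visible to the microenvironment) and external inputs (no ODE of
    their own; their values are supplied per evaluation).
    """

    name: str
    role: str = "internal"
    initial_value: float = 0.0

    def __post_init__(self):
        if self.role not in SPECIES_ROLES:
            raise ValueError(f"unknown species role {self.role!r}")
        if self.initial_value < 0:
            raise ValueError(f"initial_value of {self.name} must be >= 0")


@dataclass(frozen=True)
class RateLaw:
    """Structured rate law; see module docstring for the three kinds."""

    kind: str
    rate_constant: str
    reactant_orders: Mapping[str, int] = field(default_factory=dict)
    saturating_species: str | None = None
    half_constant: str | None = None

    def __post_init__(self):
        if self.kind not in RATE_KINDS:
            raise ValueError(f"unknown rate-law kind {self.kind!r}")
        for sp, order in self.reactant_orders.items():
            if order < 1:
                raise ValueError(f"order of {sp} must be >= 1")
        if self.kind == "saturating" and (
            self.saturating_species is None or self.half_constant is None
        ):
            raise ValueError("saturating law needs saturating_species and half_constant")


@dataclass(frozen=True)
class Reaction:
    """A named reaction: rate law plus signed stoichiometry.

    Consumed species carry negative coefficients, produced species positive
    ones.  ``provenance`` records whether the reaction is taken from a
    printed table row or reconstructed from the pathway description.
    """

    name: str
    rate: RateLaw
    stoichiometry: Mapping[str, int]
    provenance: str = "printed"
    description: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.name} has empty stoichiometry")


@dataclass
class ReactionNetwork:
    species: list[SpeciesSpec]
    reactions: list[Reaction]
    parameters: dict[str, float]

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")

    @property
    def dynamical_species(self) -> list[str]:
        return [s.name for s in self.species if s.role != "external-input"]

    @property
    def input_species(self) -> list[str]:
        return [s.name for s in self.species if s.role == "external-input"]

    def species_spec(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def initial_state(self) -> np.ndarray:
        return np.array(
            [self.species_spec(n).initial_value for n in self.dynamical_species]
        )


@dataclass
class Trajectory:
    """Solution of a network ODE: times (h) by species (a.u.)."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    species: list[str]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def at(self, t: float) -> np.ndarray:
        idx = np.searchsorted(self.times, t)
        if idx >= len(self.times) or not np.isclose(self.times[idx], t):
            raise KeyError(f"time {t} not in trajectory")
        return self.values[idx]


@dataclass
class ValidationReport:
    undefined_species: list[str] = field(default_factory=list)
    undefined_parameters: list[str] = field(default_factory=list)
    unreferenced_species: list[str] = field(default_factory=list)
    duplicate_reaction_names: list[str] = field(default_factory=list)

    @property
    def errors(self) -> list[str]:
        return self.undefined_species + self.undefined_parameters

    @property
    def warnings(self) -> list[str]:
        return self.unreferenced_species + self.duplicate_reaction_names

    @property
    def ok(self) -> bool:
        """True when no undefined symbols; duplicates/unreferenced warn only."""
        return not self.errors

    @property
    def clean(self) -> bool:
        return not self.errors and not self.unreferenced_species


def evaluate_rate(
    rate: RateLaw,
    concentrations: Mapping[str, float],
    parameters: Mapping[str, float],
) -> float:
    """Evaluate one rate law at the given concentrations (a.u./h).

    Raises :class:`NetworkDefinitionError` naming the missing symbol and
    ValueError on negative concentrations.
    """

    def conc(name: str) -> float:
        try:
            c = concentrations[name]
        except KeyError:
            raise NetworkDefinitionError(f"species {name!r} missing from concentrations")
        if c < 0:
            raise ValueError(f"negative concentration for species {name!r}")
        return c

    def param(name: str) -> float:
        try:
            return parameters[name]
        except KeyError:
            raise NetworkDefinitionError(f"parameter {name!r} undefined")

    k = param(rate.rate_constant)
    if rate.kind == "constant_source":
        return k
    flux = k
    for sp, order in rate.reactant_orders.items():
        flux *= conc(sp) ** order
    if rate.kind == "saturating":
        x = conc(rate.saturating_species)
        K = param(rate.half_constant)
        denom = x + K
        flux *= 0.0 if denom == 0 else x / denom
    return flux


def check_network(network: ReactionNetwork) -> ValidationReport:
    """Report undefined symbols, unreferenced species and duplicate names."""
    known = {s.name for s in network.species}
    report = ValidationReport()
    referenced: set[str] = set()
    seen_names: set[str] = set()
    for rxn in network.reactions:
        if rxn.name in seen_names and rxn.name not in report.duplicate_reaction_names:
            report.duplicate_reaction_names.append(rxn.name)
        seen_names.add(rxn.name)
        symbols = set(rxn.rate.reactant_orders) | set(rxn.stoichiometry)
        if rxn.rate.saturating_species:
            symbols.add(rxn.rate.saturating_species)
        for sp in sorted(symbols):
            referenced.add(sp)
            if sp not in known and sp not in report.undefined_species:
                report.undefined_species.append(sp)
        for pname in filter(None, (rxn.rate.rate_constant, rxn.rate.half_constant)):
            if pname not in network.parameters and pname not in report.undefined_parameters:
                report.undefined_parameters.append(pname)
    for s in network.species:
        if s.name not in referenced:
            report.unreferenced_species.append(s.name)
    return report


class _CompiledRHS:
    """Vectorized right-hand side: dx_s/dt = sum_r stoich(r,s) * rate_r."""

    def __init__(self, network: ReactionNetwork):
        report = check_network(network)
        if not report.ok:
            raise NetworkDefinitionError(
                "network fails validation: " + ", ".join(report.errors)
            )
        self.network = network
        self.dyn = network.dynamical_species
        self.inputs = network.input_species
        self.n_dyn = len(self.dyn)
        self.n_in = len(self.inputs)
        order = self.dyn + self.inputs  # concatenated z = (x, u)
        index = {name: i for i, name in enumerate(order)}
        R, N = len(network.reactions), len(order)
        self.exponents = np.zeros((R, N))
        self.sat_idx = np.full(R, -1, dtype=int)
        self.sat_K_name = [None] * R
        self.k_name = [r.rate.rate_constant for r in network.reactions]
        self.stoich = np.zeros((R, self.n_dyn))
        for ri, rxn in enumerate(network.reactions):
            for sp, o in rxn.rate.reactant_orders.items():
                self.exponents[ri, index[sp]] += o
            if rxn.rate.kind == "saturating":
                self.sat_idx[ri] = index[rxn.rate.saturating_species]
                self.sat_K_name[ri] = rxn.rate.half_constant
            for sp, coeff in rxn.stoichiometry.items():
                di = index[sp]
                if di < self.n_dyn:  # external inputs receive no derivative
                    self.stoich[ri, di] += coeff
        self.bind_parameters(network.parameters)

    def bind_parameters(self, parameters: Mapping[str, float]) -> None:
        try:
            self.k = np.array([parameters[n] for n in self.k_name])
            self.sat_K = np.array(
                [parameters[n] if n is not None else 1.0 for n in self.sat_K_name]
            )
        except KeyError as exc:
            raise NetworkDefinitionError(f"parameter {exc.args[0]!r} undefined")

    def rates(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        z = np.maximum(np.concatenate([x, u]), 0.0)
        flux = self.k * np.prod(z[None, :] ** self.exponents, axis=1)
        mask = self.sat_idx >= 0
        if mask.any():
            xs = z[self.sat_idx[mask]]
            denom = xs + self.sat_K[mask]
            frac = np.where(denom > 0, xs / np.where(denom > 0, denom, 1.0), 0.0)
            flux[mask] *= frac
        return flux

    def __call__(self, t, x, u=None) -> np.ndarray:
        if np.shape(x) != (self.n_dyn,):
            raise ValueError(
                f"state vector has shape {np.shape(x)}, expected ({self.n_dyn},)"
            )
        if u is None:
            u = np.zeros(self.n_in)
        u = np.asarray(u, dtype=float)
        if u.shape != (self.n_in,):
            raise ValueError(f"inputs have shape {u.shape}, expected ({self.n_in},)")
        return self.rates(np.asarray(x, dtype=float), u) @ self.stoich


def assemble_rhs(network: ReactionNetwork) -> _CompiledRHS:
    """Compile the network into ``f(t, x, u) -> dx/dt``.

    State ordering follows ``network.dynamical_species``; inputs follow
    ``network.input_species``.
    """
    return _CompiledRHS(network)


def simulate_network(
    network: ReactionNetwork,
    x0: Sequence[float],
    parameters: Mapping[str, float] | None = None,
    inputs: Callable[[float], np.ndarray] | Sequence[float] | None = None,
    times: Sequence[float] = (0.0, 24.0, 48.0, 72.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the network ODEs at the requested times (hours).

    ``inputs`` may be a callable ``t -> vector``, a constant vector, or
    None (zero inputs).  Deterministic for fixed arguments.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("x0 must be nonnegative")
    rhs = assemble_rhs(network)
    if parameters is not None:
        rhs.bind_parameters(parameters)
    if inputs is None:
        ufun = lambda t: np.zeros(rhs.n_in)
    elif callable(inputs):
        ufun = inputs
    else:
        const_u = np.asarray(inputs, dtype=float)
        ufun = lambda t: const_u

    sol = solve_ivp(
        lambda t, x: rhs(t, x, ufun(t)),
        (times[0], times[-1]),
        x0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        last_good = None
        if sol.t.size:
            finite = np.all(np.isfinite(sol.y), axis=0)
            if finite.any():
                last_good = float(sol.t[finite][-1])
        raise SolverError(f"integration failed: {sol.message}", last_good)
    values = sol.y.T.copy()
    values[np.abs(values) < ZERO_FLOOR] = 0.0
    values = np.maximum(values, 0.0)
    return Trajectory(times=times, values=values, species=list(rhs.dyn))


# ---------------------------------------------------------------------------
# serialization


def _network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "species": [
            {"name": s.name, "role": s.role, "initial_value": float(s.initial_value)}
            for s in network.species
        ],
        "reactions": [
            {
                "name": r.name,
                "description": r.description,
                "provenance": r.provenance,
                "rate": {
                    "kind": r.rate.kind,
                    "rate_constant": r.rate.rate_constant,
                    "reactant_orders": dict(r.rate.reactant_orders),
                    "saturating_species": r.rate.saturating_species,
                    "half_constant": r.rate.half_constant,
                },
                "stoichiometry": dict(r.stoichiometry),
            }
            for r in network.reactions
        ],
        "parameters": {k: float(v) for k, v in network.parameters.items()},
    }


def _network_from_dict(data: dict) -> ReactionNetwork:
    species = [SpeciesSpec(**s) for s in data["species"]]
    reactions = []
    for r in data["reactions"]:
        rate = RateLaw(
            kind=r["rate"]["kind"],
            rate_constant=r["rate"]["rate_constant"],
            reactant_orders=r["rate"].get("reactant_orders") or {},
            saturating_species=r["rate"].get("saturating_species"),
            half_constant=r["rate"].get("half_constant"),
        )
        reactions.append(
            Reaction(
                name=r["name"],
                rate=rate,
                stoichiometry=r["stoichiometry"],
                provenance=r.get("provenance", "printed"),
                description=r.get("description", ""),
            )
        )
    return ReactionNetwork(species, reactions, dict(data["parameters"]))


def save_network(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_network_to_dict(network), fh, sort_keys=False)


def load_network(path) -> ReactionNetwork:
    with open(path) as fh:
        return _network_from_dict(yaml.safe_load(fh))
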