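"""The coupled macro-loop: chemistry → fields → decisions → mechanics.

Each macro-step advances the biology by ``hours_per_step`` hours:

1. every cell integrates its intracellular ODEs, with external inputs set
   to the surface-averaged concentrations of the signals it receives
   (cancer cells read CAF TGFβ and CXCL12; CAFs read cancer TGFβ and LIF);
2. secreted species (TGFβ, LIF, CXCL12, SNAIL, MMP) are deposited into
   their fields as point sources, and uptake is removed;
3. all diffusing fields relax (explicit scheme, automatic sub-stepping);
4. the ECM field is generated/degraded against local MMP;
5. every cancer cell re-evaluates its state from CXCL12, SNAIL and ECM
   thresholds; 6. due proliferative cells divide; 7. migratory cells move
   under the force balance; 8. end-of-step values seed the next step.

Two clocks coexist: the biological macro-step (default 7.2 h, so ten
steps span a 72-hour experiment) and the mechanical/diffusion sub-step
used inside a macro-step; both are configurable presets.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .agents import (
    CANCER_RADIUS_UM,
    CellAgent,
    CellState,
    MechanicsParams,
    Thresholds,
    advance_cells,
    classify_state,
    environment_force,
    net_pairwise_forces,
)
from .cell_models import CellModelSpec, build_caf_network, build_cancer_cell_network
from .reaction_network import assemble_rhs, simulate_network
from .spatial import (
    CM_PER_UM,
    DiffusionSpec,
    FieldGrid,
    build_domain,
    deposit_secretion,
    diffuse,
    mean_surface_concentration,
    surface_uptake,
)
from .synthetic_data import make_fixture_tumor

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "Simulator",
    "initialize",
    "step",
    "run",
    "resume",
    "mean_displacement",
    "save_state",
    "load_state",
]

#: which secreted species of each cell type feeds which field
SECRETION_MAP = {
    "cancer": {"xu1": "TGFb_c", "xu2": "LIF_c", "MMPs": "MMP"},
    "caf": {"xu3": "TGFb_f", "xu4": "CXCL12", "x24": "SNAIL"},
}
#: which field supplies each external input of each cell type
INPUT_MAP = {
    "cancer": {"xu3": "TGFb_f", "xu4": "CXCL12"},
    "caf": {"xu1": "TGFb_c", "xu2": "LIF_c"},
}


@dataclass
class SimulationConfig:
    n_cancer: int = 20
    n_caf: int = 20
    domain_radius_cm: float = 2.0
    nodes_per_axis: int = 33
    n_steps: int = 10
    hours_per_step: float = 7.2
    Ts: float = 0.05 / 3600.0     # mechanical sub-step preset (hours)
    seed: int = 0
    thresholds: Thresholds = field(default_factory=lambda: Thresholds(
        T_CXCL12=0.05, T_SNAIL=0.01, T_ECM=0.5))
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    diffusion: dict[str, DiffusionSpec] = field(default_factory=lambda: {
        "TGFb_c": DiffusionSpec(D=3.6e-3, decay=0.01),
        "LIF_c": DiffusionSpec(D=3.6e-3, decay=0.01),
        "TGFb_f": DiffusionSpec(D=3.6e-3, decay=0.01),
        "CXCL12": DiffusionSpec(D=3.6e-3, decay=0.01),
        "SNAIL": DiffusionSpec(D=1.8e-3, decay=0.01),
        "MMP": DiffusionSpec(D=1.8e-3, decay=0.02),
    })
    field_initial: dict[str, float] = field(default_factory=lambda: {"ECM": 1.0})
    ecm_a1: float = 0.0           # ECM generation rate (1/h)
    ecm_a2: float = 0.05          # ECM degradation per unit MMP (1/(a.u. h))
    secretion_rate: float = 1.0   # field mass per hour per unit species (a.u. cm^3/h)
    uptake_efficiency: float = 0.1  # fraction of the surface integral removed
    division_period_h: float = 24.0
    active_direction: str = "outward"  # outward | down-ecm-gradient
    mech_substeps: int = 24  # mechanical relaxations per macro-step

    def __post_init__(self):
        if self.n_cancer < 0 or self.n_caf < 0 or self.n_steps < 0:
            raise ValueError("counts and n_steps must be >= 0")
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        if isinstance(self.mechanics, dict):
            self.mechanics = MechanicsParams(**self.mechanics)
        self.diffusion = {
            k: (DiffusionSpec(**v) if isinstance(v, dict) else v)
            for k, v in self.diffusion.items()
        }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SimulationState:
    cells: list[CellAgent]
    grid: FieldGrid
    step: int
    rng: np.random.Generator
    next_id: int
    hours: float = 0.0


class Simulator:
    """Holds the compiled cell models and advances a :class:`SimulationState`."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.specs: dict[str, CellModelSpec] = {
            "cancer": build_cancer_cell_network(),
            "caf": build_caf_network(),
        }
        self.rhs = {k: assemble_rhs(s.network) for k, s in self.specs.items()}

    # -- initialization ----------------------------------------------------
    def initialize(self) -> SimulationState:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        placement_seed = int(rng.integers(0, 2**31 - 1))
        cells = make_fixture_tumor(cfg.n_cancer, cfg.n_caf,
                                   cfg.domain_radius_cm, seed=placement_seed)
        for c in cells:
            c.intracellular = self.specs[c.kind].network.initial_state()
            c.state = CellState.QUIESCENT
        grid = build_domain(cfg.domain_radius_cm, cfg.nodes_per_axis,
                            initial_values=cfg.field_initial)
        return SimulationState(cells=cells, grid=grid, step=0, rng=rng,
                               next_id=len(cells))

    # -- one macro-step ----------------------------------------------------
    def step(self, state: SimulationState) -> SimulationState:
        cfg = self.config
        dt = cfg.hours_per_step
        grid = state.grid
        snapshot = _snapshot(state)
        try:
            # (1) intracellular chemistry with surface-uptake inputs
            uptakes: dict[int, dict[str, float]] = {}
            for c in state.cells:
                spec = self.specs[c.kind]
                center_cm = c.position * CM_PER_UM
                u = {}
                removal = {}
                for input_name, field_name in INPUT_MAP[c.kind].items():
                    integral = surface_uptake(grid, field_name, center_cm, c.radius)
                    area = 4 * np.pi * (c.radius * CM_PER_UM) ** 2
                    u[input_name] = integral / area
                    removal[field_name] = integral
                uptakes[c.id] = removal
                traj = simulate_network(
                    spec.network, np.maximum(c.intracellular, 0.0),
                    inputs=spec.input_vector(u),
                    times=(0.0, dt), rtol=1e-6, atol=1e-9,
                )
                c.intracellular = traj.values[-1]

            # (2) secretion deposits and uptake removal
            for c in state.cells:
                spec = self.specs[c.kind]
                dyn = spec.network.dynamical_species
                center_cm = c.position * CM_PER_UM
                for species, field_name in SECRETION_MAP[c.kind].items():
                    level = c.intracellular[dyn.index(species)]
                    if level > 0:
                        deposit_secretion(grid, field_name, center_cm,
                                          cfg.secretion_rate * level, dt)
                for field_name, integral in uptakes[c.id].items():
                    if integral > 0:
                        deposit_secretion(grid, field_name, center_cm,
                                          -cfg.uptake_efficiency * integral, dt)
                        np.maximum(grid.fields[field_name], 0.0,
                                   out=grid.fields[field_name])

            # (3) field relaxation, (4) ECM dynamics
            for name, dspec in cfg.diffusion.items():
                diffuse(grid, name, dspec, dt)
            _update_ecm_substepped(grid, cfg.ecm_a1, cfg.ecm_a2, dt)

            # (5) state decisions
            centroid = _cancer_centroid(state.cells)
            for c in state.cells:
                if c.kind != "cancer":
                    continue
                center_cm = c.position * CM_PER_UM
                u_cx = mean_surface_concentration(grid, "CXCL12", center_cm, c.radius)
                u_sn = mean_surface_concentration(grid, "SNAIL", center_cm, c.radius)
                ecm_local = grid.interpolate("ECM", center_cm)
                c.state = classify_state(c, u_cx, u_sn, ecm_local, cfg.thresholds)

            # (6) division
            now = state.hours + dt
            newborn = []
            for c in state.cells:
                if (c.kind == "cancer" and c.state == CellState.PROLIFERATIVE
                        and now - c.last_division_h >= cfg.division_period_h):
                    c.last_division_h = now
                    from .agents import divide
                    _, daughter = divide(c, state.rng, new_id=state.next_id)
                    daughter.birth_step = state.step + 1
                    daughter.last_division_h = now
                    state.next_id += 1
                    newborn.append(daughter)
            for d in newborn:
                d.intracellular = (d.intracellular if d.intracellular is not None
                                   else self.specs[d.kind].network.initial_state())
            state.cells.extend(newborn)

            # (7) mechanics: environment forces held over the macro-step
            # (fields are frozen during it); contact forces re-resolved on
            # the fast mechanical clock so overlaps relax without overshoot
            env: dict[int, np.ndarray] = {}
            for c in state.cells:
                if c.kind != "cancer" or c.state != CellState.MIGRATORY:
                    continue
                center_cm = c.position * CM_PER_UM
                grad_per_um = grid.gradient("ECM", center_cm) * CM_PER_UM
                u_sn = mean_surface_concentration(grid, "SNAIL", center_cm, c.radius)
                direction = _active_direction(c, centroid, grad_per_um, cfg)
                env[c.id] = environment_force(
                    c, grad_per_um, u_sn, direction, cfg.mechanics)
            dt_mech = dt / max(1, cfg.mech_substeps)
            for _ in range(max(1, cfg.mech_substeps)):
                forces = net_pairwise_forces(state.cells, cfg.mechanics)
                for cid, f in env.items():
                    forces[cid] = forces[cid] + f
                advance_cells(state.cells, forces, cfg.mechanics.gamma_cs, dt_mech)
            _clamp_to_domain(state.cells, cfg.domain_radius_cm)

            state.step += 1
            state.hours = now
            return state
        except Exception:
            _restore(state, snapshot)  # roll back to step entry
            raise


def _cancer_centroid(cells) -> np.ndarray:
    pos = [c.position for c in cells if c.kind == "cancer"]
    return np.mean(pos, axis=0) if pos else np.zeros(3)


def _active_direction(cell, centroid, ecm_grad, cfg) -> np.ndarray:
    if cfg.active_direction == "down-ecm-gradient":
        n = -ecm_grad
    else:  # outward invasion: from the tumor centroid through the cell
        n = cell.position - centroid
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        n = np.array([0.0, 0.0, 1.0])
        norm = 1.0
    return n / norm


def _update_ecm_substepped(grid, a1, a2, dt, n_sub=10):
    from .spatial import update_ecm

    for _ in range(n_sub):
        update_ecm(grid, a1, a2, dt / n_sub)


def _clamp_to_domain(cells, radius_cm):
    limit = radius_cm / CM_PER_UM
    for c in cells:
        r = np.linalg.norm(c.position)
        if r + c.radius >= limit:
            c.position = c.position * ((limit - c.radius) * 0.999 / r)


def _snapshot(state: SimulationState) -> dict:
    return {
        "cells": [(c.id, c.kind, c.position.copy(), c.radius, c.state,
                   None if c.intracellular is None else c.intracellular.copy(),
                   c.birth_step, c.last_division_h) for c in state.cells],
        "fields": {k: v.copy() for k, v in state.grid.fields.items()},
        "step": state.step,
        "hours": state.hours,
        "next_id": state.next_id,
        "rng": state.rng.bit_generator.state,
    }


def _restore(state: SimulationState, snap: dict) -> None:
    state.cells = [
        CellAgent(id=i, kind=k, position=p, radius=r, state=s, intracellular=ic,
                  birth_step=bs, last_division_h=ld)
        for (i, k, p, r, s, ic, bs, ld) in snap["cells"]
    ]
    state.grid.fields = snap["fields"]
    state.step = snap["step"]
    state.hours = snap["hours"]
    state.next_id = snap["next_id"]
    state.rng.bit_generator.state = snap["rng"]


# -- module-level convenience wrappers --------------------------------------

def initialize(config: SimulationConfig) -> SimulationState:
    return Simulator(config).initialize()


def step(state: SimulationState, config: SimulationConfig) -> SimulationState:
    return Simulator(config).step(state)


@dataclass
class RunResult:
    config: SimulationConfig
    history: pd.DataFrame         # per step per cell: positions and states
    final_state: SimulationState

    def positions_at_step(self, k: int) -> pd.DataFrame:
        return self.history[self.history["step"] == k]


def _history_rows(state: SimulationState):
    for c in state.cells:
        yield {
            "step": state.step, "hours": state.hours, "id": c.id, "kind": c.kind,
            "state": c.state.value, "x": c.position[0], "y": c.position[1],
            "z": c.position[2], "radius": c.radius,
        }


def run(config: SimulationConfig, out_dir: str | None = None,
        simulator: Simulator | None = None,
        state: SimulationState | None = None,
        n_steps: int | None = None) -> RunResult:
    """Initialize (unless resuming) and advance ``n_steps`` macro-steps.

    With ``out_dir`` set, writes per-step cell tables, a run manifest
    (config digest, seed, version) and a summary table.
    """
    sim = simulator or Simulator(config)
    if state is None:
        state = sim.initialize()
    n_steps = config.n_steps if n_steps is None else n_steps
    rows = list(_history_rows(state))
    for _ in range(n_steps):
        state = sim.step(state)
        rows.extend(_history_rows(state))
    history = pd.DataFrame(rows)
    result = RunResult(config=config, history=history, final_state=state)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        history.to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)
        disp = mean_displacement(result)
        disp.to_csv(os.path.join(out_dir, "mean_displacement.tsv"), sep="\t")
        manifest = {
            "config": config.to_dict(),
            "config_digest": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "n_steps_run": int(n_steps),
        }
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        save_state(state, os.path.join(out_dir, "state"))
    return result


def resume(state: SimulationState, config: SimulationConfig,
           n_steps: int, out_dir: str | None = None) -> RunResult:
    return run(config, out_dir=out_dir, state=state, n_steps=n_steps)


def mean_displacement(result: RunResult,
                      sample_hours: list[float] | None = None) -> pd.Series:
    """Mean straight-line displacement of founder cancer cells, in mm.

    Displacement of each cancer cell present at time zero is
    ``|position(t) - position(0)|``; the mean is reported at each sampled
    time (default: every recorded step).
    """
    h = result.history
    founders = h[(h["step"] == 0) & (h["kind"] == "cancer")]
    origin = founders.set_index("id")[["x", "y", "z"]]
    out = {}
    for hours, group in h[h["kind"] == "cancer"].groupby("hours"):
        g = group[group["id"].isin(origin.index)].set_index("id")
        d = np.linalg.norm(g[["x", "y", "z"]].values - origin.loc[g.index].values,
                           axis=1)
        out[float(hours)] = d.mean() / 1000.0  # µm -> mm
    series = pd.Series(out).sort_index()
    series.index.name = "hours"
    series.name = "mean_displacement_mm"
    if sample_hours is not None:
        series = series.reindex(
            [min(series.index, key=lambda t: abs(t - s)) for s in sample_hours]
        )
    return series


# -- state serialization -----------------------------------------------------

def save_state(state: SimulationState, directory: str) -> None:
    """Serialize a simulation state so a run can be resumed bit-identically."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for c in state.cells:
        rows.append({
            "id": c.id, "kind": c.kind, "state": c.state.value,
            "x": repr(float(c.position[0])), "y": repr(float(c.position[1])),
            "z": repr(float(c.position[2])), "radius": c.radius,
            "birth_step": c.birth_step,
            "last_division_h": repr(float(c.last_division_h)),
            "intracellular": ",".join(repr(float(v)) for v in c.intracellular),
        })
    pd.DataFrame(rows).to_csv(os.path.join(directory, "cells.tsv"),
                              sep="\t", index=False)
    for name, arr in state.grid.fields.items():
        np.save(os.path.join(directory, f"field_{name}.npy"), arr)
    meta = {
        "step": state.step,
        "hours": state.hours,
        "next_id": state.next_id,
        "radius": state.grid.radius,
        "nodes_per_axis": state.grid.n,
        "rng_state": _jsonify(state.rng.bit_generator.state),
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_state(directory: str) -> SimulationState:
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    grid = build_domain(meta["radius"], meta["nodes_per_axis"], fields=())
    for fn in sorted(os.listdir(directory)):
        if fn.startswith("field_") and fn.endswith(".npy"):
            grid.fields[fn[len("field_"):-4]] = np.load(os.path.join(directory, fn))
    # dtype=str + python float(): exact round-trip of repr-formatted values
    table = pd.read_csv(os.path.join(directory, "cells.tsv"), sep="\t", dtype=str)
    cells = []
    for _, row in table.iterrows():
        cells.append(CellAgent(
            id=int(row["id"]), kind=row["kind"],
            position=np.array([float(row["x"]), float(row["y"]), float(row["z"])]),
            radius=float(row["radius"]), state=CellState(row["state"]),
            intracellular=np.array([float(v) for v in
                                    str(row["intracellular"]).split(",")]),
            birth_step=int(row["birth_step"]),
            last_division_h=float(row["last_division_h"]),
        ))
    rng = np.random.default_rng()
    st = meta["rng_state"]
    st["state"]["state"] = int(st["state"]["state"])
    st["state"]["inc"] = int(st["state"]["inc"])
    rng.bit_generator.state = st
    return SimulationState(cells=cells, grid=grid, step=int(meta["step"]),
                          rng=rng, next_id=int(meta["next_id"]),
                          hours=float(meta["hours"]))
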