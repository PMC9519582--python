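"""Cell agents: behavioral state machine and center-based mechanics.

Each cancer cell is a sphere (radius 8 µm) that is quiescent,
proliferative, or migratory depending on the signal levels sampled at its
surface: it turns migratory when SNAIL exceeds its threshold while the
local ECM has been degraded below its threshold (detachment), otherwise
proliferative when CXCL12 exceeds its threshold, otherwise quiescent.
CAFs (radius 7 µm) are mechanically and behaviorally static.

Migratory cells move overdamped: the sum of Hertz repulsion, constant
adhesion, haptotaxis along the ECM gradient and a SNAIL-driven active
force is balanced by friction, ``V = F_total / Gamma_cs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "CellAgent",
    "CellState",
    "Thresholds",
    "MechanicsParams",
    "classify_state",
    "pairwise_force",
    "environment_force",
    "net_pairwise_forces",
    "advance_cells",
    "divide",
    "CANCER_RADIUS_UM",
    "CAF_RADIUS_UM",
]

CANCER_RADIUS_UM = 8.0
CAF_RADIUS_UM = 7.0


class CellState(str, Enum):
    QUIESCENT = "quiescent"
    PROLIFERATIVE = "proliferative"
    MIGRATORY = "migratory"


@dataclass
class CellAgent:
    id: int
    kind: str                      # "cancer" | "caf"
    position: np.ndarray           # µm
    radius: float                  # µm
    state: CellState = CellState.QUIESCENT
    intracellular: np.ndarray | None = None
    birth_step: int = 0
    last_division_h: float = 0.0

    def __post_init__(self):
        if self.kind not in ("cancer", "caf"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        self.position = np.asarray(self.position, dtype=float)
        self.state = CellState(self.state)


@dataclass
class Thresholds:
    """Signal thresholds gating the cancer-cell state decision (a.u.)."""

    T_CXCL12: float = 1.0
    T_SNAIL: float = 1.0
    T_ECM: float = 1.0

    def __post_init__(self):
        for name in ("T_CXCL12", "T_SNAIL", "T_ECM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class MechanicsParams:
    """Force-law constants.

    ``E_hat`` is the pair effective elastic modulus (per-pair, derived
    from per-cell Young moduli and Poisson ratios), ``W`` the adhesion
    energy density, ``chi`` the haptotaxis coefficient, ``eta/A0/n_hill``
    the amplitude, half-point and steepness of the SNAIL-driven active
    force, and ``gamma_cs`` the cell-substrate friction coefficient.
    """

    E_hat: float = 1.0
    W: float = 0.05
    chi: float = 0.1
    eta: float = 2.0
    A0: float = 1.0
    n_hill: float = 2.0
    gamma_cs: float = 0.25
    adhesion_range: float = 2.0  # µm beyond contact

    def __post_init__(self):
        if self.gamma_cs <= 0:
            raise ValueError("gamma_cs must be > 0")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")


def classify_state(cell: CellAgent, u_CXCL12: float, u_SNAIL: float,
                   ecm_local: float, thr: Thresholds) -> CellState:
    """Fate decision for one cancer cell; migration has precedence.

    Migratory iff SNAIL >= T_SNAIL and local ECM <= T_ECM; otherwise
    proliferative iff CXCL12 >= T_CXCL12; otherwise quiescent.
    """
    if cell.kind != "cancer":
        raise ValueError("only cancer cells change state")
    if min(u_CXCL12, u_SNAIL, ecm_local) < 0:
        raise ValueError("signal inputs must be >= 0")
    if u_SNAIL >= thr.T_SNAIL and ecm_local <= thr.T_ECM:
        return CellState.MIGRATORY
    if u_CXCL12 >= thr.T_CXCL12:
        return CellState.PROLIFERATIVE
    return CellState.QUIESCENT


def pairwise_force(ci: CellAgent, cj: CellAgent, mech: MechanicsParams,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Hertz repulsion plus constant adhesion on ``ci`` from ``cj``.

    With overlap ``delta = Ri + Rj - |ri - rj|`` and effective radius
    ``R_hat = Ri*Rj/(Ri+Rj)``: repulsion of magnitude
    ``(4/3) * E_hat * sqrt(R_hat) * delta^(3/2)`` pushes the cells apart
    when delta > 0; a constant attraction ``pi * W * R_hat`` acts while
    ``-adhesion_range < delta <= adhesion_range``.  The force on ``cj``
    is the exact negative.
    """
    if ci.id == cj.id:
        raise ValueError("pairwise force requires distinct cells")
    sep = ci.position - cj.position
    dist = float(np.linalg.norm(sep))
    if dist == 0.0:
        warnings.warn("coincident cell centers; repelling along a seeded direction")
        rng = rng or np.random.default_rng(0)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
    else:
        n = sep / dist
    delta = ci.radius + cj.radius - dist
    R_hat = ci.radius * cj.radius / (ci.radius + cj.radius)
    f = np.zeros(3)
    if delta > 0:
        f += (4.0 / 3.0) * mech.E_hat * np.sqrt(R_hat) * delta**1.5 * n
    if -mech.adhesion_range < delta <= mech.adhesion_range:
        f -= np.pi * mech.W * R_hat * n
    return f


def net_pairwise_forces(cells: list[CellAgent],
                        mech: MechanicsParams) -> dict[int, np.ndarray]:
    """Sum of pairwise forces per cell; internal forces balance exactly."""
    forces = {c.id: np.zeros(3) for c in cells}
    for i, ci in enumerate(cells):
        for cj in cells[i + 1:]:
            f = pairwise_force(ci, cj, mech)
            forces[ci.id] += f
            forces[cj.id] -= f
    return forces


def environment_force(cell: CellAgent, ecm_grad: np.ndarray, u_SNAIL: float,
                      direction: np.ndarray, mech: MechanicsParams) -> np.ndarray:
    """Haptotaxis ``-chi * grad(ECM)`` plus SNAIL-gated active force.

    The active force is ``eta * A^n / (A^n + A0^n)`` along ``direction``
    with ``A`` the SNAIL level at the cell surface.
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if not np.isclose(norm, 1.0):
        warnings.warn("active-force direction not unit length; normalizing")
        if norm == 0:
            raise ValueError("active-force direction cannot be the zero vector")
        direction = direction / norm
    A = max(float(u_SNAIL), 0.0)
    hill = 0.0
    if A > 0:
        An = A**mech.n_hill
        hill = An / (An + mech.A0**mech.n_hill)
    return -mech.chi * np.asarray(ecm_grad, dtype=float) + mech.eta * hill * direction


def advance_cells(cells: list[CellAgent], net_forces: dict[int, np.ndarray],
                  gamma_cs: float, dt: float) -> None:
    """Overdamped update ``position += (F / gamma_cs) * dt``; migratory only."""
    if gamma_cs <= 0:
        raise ValueError("gamma_cs must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    for c in cells:
        if c.kind == "cancer" and c.state == CellState.MIGRATORY:
            c.position = c.position + np.asarray(net_forces[c.id]) / gamma_cs * dt


def divide(cell: CellAgent, rng: np.random.Generator,
           new_id: int | None = None) -> tuple[CellAgent, CellAgent]:
    """Split a proliferative cell; the daughter starts quiescent.

    The daughter is placed one cell radius away in a uniformly random
    direction and inherits a copy of the intracellular state.
    """
    if cell.state != CellState.PROLIFERATIVE:
        raise ValueError("only proliferative cells divide")
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    daughter = CellAgent(
        id=new_id if new_id is not None else cell.id + 1_000_000,
        kind=cell.kind,
        position=cell.position + cell.radius * v,
        radius=cell.radius,
        state=CellState.QUIESCENT,
        intracellular=None if cell.intracellular is None else cell.intracellular.copy(),
        birth_step=cell.birth_step,
    )
    return cell, daughter
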