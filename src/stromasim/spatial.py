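"""Diffusive signal fields and ECM on a spherical microenvironment.

The tumor microenvironment is a ball (default radius 2 cm) discretized on
a regular Cartesian grid with a sphere mask.  Each diffusing signal
(cancer/CAF TGFβ, LIF, CXCL12, SNAIL, MMP) is a nodal scalar field evolved
with an explicit finite-difference scheme

    du/dt = D * laplacian(u) - decay * u

subject to a Dirichlet condition at the domain boundary.  The Dirichlet
value is held on the ghost layer of outside nodes adjacent to the ball, so
every inside node evolves; this places the effective zero surface at the
sphere rather than one grid cell inside it, which is what keeps the
fundamental-mode decay rate accurate on coarse grids.

Cells couple to the fields by surface integrals (uptake over a spherical
quadrature), point-source deposition (secretion), and the local ECM update
``d[ECM]/dt = a1*[ECM] - a2*[MMP]*[ECM]``.

Units: grid geometry in cm, time in hours, cell radii in µm
(:data:`CM_PER_UM` converts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FieldGrid",
    "DiffusionSpec",
    "build_domain",
    "step_diffusion",
    "surface_uptake",
    "deposit_secretion",
    "update_ecm",
    "field_mass",
    "CM_PER_UM",
    "SIGNAL_FIELDS",
]

CM_PER_UM = 1e-4

#: canonical field names: four intercellular signals, SNAIL, ECM and MMP
SIGNAL_FIELDS = ("TGFb_c", "LIF_c", "TGFb_f", "CXCL12", "SNAIL", "ECM", "MMP")


class GeometryError(ValueError):
    """A cell or probe point lies outside the spherical domain."""


class StabilityError(ValueError):
    def __init__(self, message, suggested_substeps):
        super().__init__(message)
        self.suggested_substeps = suggested_substeps


@dataclass
class DiffusionSpec:
    """Per-signal transport constants: D (cm^2/h), sink rate (1/h), BC value."""

    D: float = 3.6e-3
    decay: float = 0.0
    dirichlet_value: float = 0.0

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("diffusion coefficient must be >= 0")


@dataclass
class FieldGrid:
    radius: float                  # cm
    n: int                         # nodes per axis
    axis: np.ndarray               # node coordinates, one axis
    mask: np.ndarray               # inside-sphere indicator
    boundary: np.ndarray           # outside ghost layer adjacent to the ball
    fields: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def spacing(self) -> float:
        return float(self.axis[1] - self.axis[0])

    def add_field(self, name: str, value: float = 0.0) -> np.ndarray:
        arr = np.full((self.n,) * 3, float(value))
        arr[~self.mask] = 0.0
        self.fields[name] = arr
        return arr

    def node_index(self, point_cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fractional grid coordinates of a point (cm); raises outside the cube."""
        p = np.asarray(point_cm, dtype=float)
        if np.any(np.abs(p) >= self.radius):
            raise GeometryError(f"point {p} outside the grid")
        frac = (p + self.radius) / self.spacing
        base = np.floor(frac).astype(int)
        return base, frac - base

    def interpolate(self, name: str, point_cm) -> float:
        """Trilinear interpolation of a field at a point (cm)."""
        base, w = self.node_index(np.asarray(point_cm, dtype=float))
        f = self.fields[name]
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = ((w[0] if dx else 1 - w[0])
                          * (w[1] if dy else 1 - w[1])
                          * (w[2] if dz else 1 - w[2]))
                    out += wt * f[base[0] + dx, base[1] + dy, base[2] + dz]
        return float(out)

    def gradient(self, name: str, point_cm) -> np.ndarray:
        """Gradient of a field at a point (per cm).

        Central differences; falls back to one-sided differences next to
        the grid edge.
        """
        p = np.asarray(point_cm, dtype=float)
        h = self.spacing
        g = np.zeros(3)
        lim = self.radius - 1e-9
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            hi = p + e if abs(p[ax] + h) < lim else p
            lo = p - e if abs(p[ax] - h) < lim else p
            span = hi[ax] - lo[ax]
            if span == 0:
                continue
            g[ax] = (self.interpolate(name, hi) - self.interpolate(name, lo)) / span
        return g


def build_domain(radius: float = 2.0, nodes_per_axis: int = 33,
                 fields: tuple[str, ...] = SIGNAL_FIELDS,
                 initial_values: dict[str, float] | None = None) -> FieldGrid:
    """Discretize the ball of the given radius on an odd regular grid."""
    if nodes_per_axis < 9 or nodes_per_axis % 2 == 0:
        raise ValueError("nodes_per_axis must be odd and >= 9 (center node exists)")
    axis = np.linspace(-radius, radius, nodes_per_axis)
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    r2 = X**2 + Y**2 + Z**2
    mask = r2 < radius**2
    outside = ~mask
    adjacent = np.zeros_like(mask)
    for ax in range(3):
        for sh in (1, -1):
            adjacent |= np.roll(mask, sh, axis=ax)
    boundary = outside & adjacent
    grid = FieldGrid(radius=float(radius), n=nodes_per_axis, axis=axis,
                     mask=mask, boundary=boundary)
    initial_values = initial_values or {}
    for name in fields:
        grid.add_field(name, initial_values.get(name, 0.0))
    return grid


def _laplacian(u: np.ndarray, h: float) -> np.ndarray:
    lap = -6.0 * u
    for ax in range(3):
        lap += np.roll(u, 1, axis=ax) + np.roll(u, -1, axis=ax)
    return lap / (h * h)


def step_diffusion(grid: FieldGrid, signal: str, spec: DiffusionSpec,
                   dt: float) -> FieldGrid:
    """One explicit diffusion(+decay) step; mutates and returns the grid.

    Raises :class:`StabilityError` proposing a sub-step count when
    ``D*dt/h^2 > 1/6``.
    """
    h = grid.spacing
    if spec.D > 0:
        courant = spec.D * dt / (h * h)
        if courant > 1.0 / 6.0 + 1e-12:
            n_sub = math.ceil(6.0 * courant)
            raise StabilityError(
                f"D*dt/h^2 = {courant:.3g} > 1/6; split dt into {n_sub} sub-steps",
                n_sub,
            )
    u = grid.fields[signal]
    u[~grid.mask] = spec.dirichlet_value  # ghost layer carries the BC
    un = u + dt * (spec.D * _laplacian(u, h) - spec.decay * u)
    un[~grid.mask] = spec.dirichlet_value
    np.maximum(un, 0.0, out=un)
    grid.fields[signal] = un
    return grid


def diffuse(grid: FieldGrid, signal: str, spec: DiffusionSpec, dt: float) -> FieldGrid:
    """Diffuse over ``dt``, automatically sub-stepping for stability."""
    h = grid.spacing
    n_sub = 1
    if spec.D > 0:
        n_sub = max(1, math.ceil(spec.D * dt / (h * h) * 6.0))
    for _ in range(n_sub):
        step_diffusion(grid, signal, spec, dt / n_sub)
    return grid


def field_mass(grid: FieldGrid, signal: str) -> float:
    """Total field mass: sum of nodal values times cell volume (a.u.*cm^3)."""
    return float(grid.fields[signal][grid.mask].sum() * grid.spacing**3)


# 26 symmetric quadrature directions: faces, edges, corners of the cube
_DIRS = []
for dx in (-1, 0, 1):
    for dy in (-1, 0, 1):
        for dz in (-1, 0, 1):
            if (dx, dy, dz) != (0, 0, 0):
                v = np.array([dx, dy, dz], dtype=float)
                _DIRS.append(v / np.linalg.norm(v))
QUADRATURE_DIRECTIONS = np.array(_DIRS)
del _DIRS


def surface_uptake(grid: FieldGrid, signal: str, center_cm,
                   cell_radius_um: float) -> float:
    """Surface integral of a field over a cell sphere (a.u.*cm^2).

    The field is sampled at 26 symmetric directions on the cell surface
    and summed with equal area weights; for a uniform field this returns
    ``c * 4*pi*R^2`` and odd (linear) variations cancel by symmetry.
    """
    center = np.asarray(center_cm, dtype=float)
    R = cell_radius_um * CM_PER_UM
    if np.linalg.norm(center) + R >= grid.radius:
        raise GeometryError("cell not entirely inside the domain")
    area = 4.0 * np.pi * R * R
    total = 0.0
    for d in QUADRATURE_DIRECTIONS:
        total += grid.interpolate(signal, center + R * d)
    return total / len(QUADRATURE_DIRECTIONS) * area


def mean_surface_concentration(grid: FieldGrid, signal: str, center_cm,
                               cell_radius_um: float) -> float:
    """Surface-averaged concentration (a.u.): uptake integral / cell area."""
    R = cell_radius_um * CM_PER_UM
    return surface_uptake(grid, signal, center_cm, cell_radius_um) / (4 * np.pi * R * R)


def deposit_secretion(grid: FieldGrid, signal: str, center_cm, rate: float,
                      dt: float) -> FieldGrid:
    """Deposit ``rate*dt`` of field mass at a point source (trilinear weights)."""
    center = np.asarray(center_cm, dtype=float)
    if np.linalg.norm(center) >= grid.radius:
        raise GeometryError("secretion source outside the domain")
    base, w = grid.node_index(center)
    if rate == 0.0:
        return grid
    amount = rate * dt / grid.spacing**3  # nodal value increment per unit weight
    f = grid.fields[signal]
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wt = ((w[0] if dx else 1 - w[0])
                      * (w[1] if dy else 1 - w[1])
                      * (w[2] if dz else 1 - w[2]))
                f[base[0] + dx, base[1] + dy, base[2] + dz] += wt * amount
    return grid


def update_ecm(grid: FieldGrid, a1: float, a2: float, dt: float,
               ecm: str = "ECM", mmp: str = "MMP") -> FieldGrid:
    """Explicit ECM update: ECM += dt*(a1*ECM - a2*MMP*ECM), floored at 0."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    E = grid.fields[ecm]
    M = grid.fields[mmp]
    En = E + dt * (a1 * E - a2 * M * E)
    np.maximum(En, 0.0, out=En)
    En[~grid.mask] = 0.0
    grid.fields[ecm] = En
    return grid


def dump_fields(grid: FieldGrid, path, step: int | None = None) -> None:
    """Write all fields as a flat table: node index, x, y, z, signal, value."""
    import pandas as pd

    idx = np.argwhere(grid.mask)
    coords = grid.axis[idx]
    frames = []
    for name, f in grid.fields.items():
        frames.append(pd.DataFrame({
            "i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
            "signal": name, "value": f[grid.mask],
        }))
    table = pd.concat(frames, ignore_index=True)
    if step is not None:
        table.insert(0, "step", step)
    table.to_csv(path, sep="\t", index=False)
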