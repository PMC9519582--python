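"""Generators for every input the pipeline needs, with no downloads.

Expression time courses emulate public 4-point microarray series (samples
at 0/24/48/72 h of SMAD7, TGFβ, LIF and CXCL12 fold changes): the cell
model is simulated under constant paracrine drive, observables are mapped
to fold changes, and multiplicative log-normal noise (default sd 5%,
matching ratio-scaled expression data) is applied with the t=0 column
re-anchored to exactly 1.  Fixture tumors provide seeded, non-overlapping
cell placements for the spatial and mechanical layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import CANCER_RADIUS_UM, CAF_RADIUS_UM, CellAgent
from .cell_models import CellModelSpec, GENES, OBS_TIMES, observables
from .reaction_network import simulate_network
from .spatial import CM_PER_UM

__all__ = [
    "TimecourseObservations",
    "generate_timecourse",
    "perturbed_truth",
    "make_fixture_tumor",
    "write_observations",
    "read_observations",
]


@dataclass
class TimecourseObservations:
    """Gene x time fold-change table plus its noise model and seed."""

    values: pd.DataFrame            # index genes, columns times (h)
    noise_sd: float
    seed: int | None

    def __post_init__(self):
        t0 = self.values.columns[0]
        if not np.allclose(self.values[t0], 1.0):
            raise ValueError("fold changes must equal 1 at t=0")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("fold changes must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def times(self) -> np.ndarray:
        return np.array([float(c) for c in self.values.columns])


def generate_timecourse(
    spec: CellModelSpec,
    true_params: dict[str, float] | None = None,
    times=OBS_TIMES,
    noise_sd: float = 0.05,
    seed: int | None = None,
    inputs: dict[str, float] | None = None,
) -> TimecourseObservations:
    """Simulate a cell model and emit noisy fold-change observations."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    net = spec.network
    params = dict(net.parameters)
    if true_params:
        params.update(true_params)
    traj = simulate_network(net, net.initial_state(), parameters=params,
                            inputs=spec.input_vector(inputs), times=times)
    fc = observables(spec, traj, tuple(times))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.exp(rng.normal(0.0, noise_sd, size=fc.shape))
        fc = fc * noise
    fc.iloc[:, 0] = 1.0  # re-anchor the fold-change baseline
    return TimecourseObservations(values=fc, noise_sd=noise_sd, seed=seed)


def perturbed_truth(
    spec: CellModelSpec,
    free_parameters: list[str],
    factor_range: tuple[float, float] = (0.5, 2.0),
    seed: int | None = None,
) -> dict[str, float]:
    """Multiply each free parameter by an independent U(factor_range) draw."""
    lo, hi = factor_range
    if lo <= 0 or hi <= 0:
        raise ValueError("factor_range must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    for name in free_parameters:
        out[name] = spec.network.parameters[name] * rng.uniform(lo, hi)
    return out


def make_fixture_tumor(
    n_cancer: int,
    n_caf: int,
    radius_cm: float = 2.0,
    seed: int | None = None,
    max_rejections: int = 10_000,
) -> list[CellAgent]:
    """Seeded non-overlapping cell placement inside the spherical domain.

    Positions are in µm; pairwise center distances are kept above half the
    sum of radii (no cell overlaps another by more than 50%).
    """
    rng = np.random.default_rng(seed)
    radius_um = radius_cm / CM_PER_UM
    cells: list[CellAgent] = []
    kinds = ["cancer"] * n_cancer + ["caf"] * n_caf
    rejections = 0
    for i, kind in enumerate(kinds):
        r_cell = CANCER_RADIUS_UM if kind == "cancer" else CAF_RADIUS_UM
        while True:
            p = rng.uniform(-radius_um, radius_um, size=3)
            if np.linalg.norm(p) + r_cell >= radius_um:
                continue
            if all(np.linalg.norm(p - c.position) >= 0.5 * (r_cell + c.radius)
                   for c in cells):
                break
            rejections += 1
            if rejections > max_rejections:
                raise RuntimeError(
                    f"placement failed after {max_rejections} rejections: "
                    "domain too dense"
                )
        cells.append(CellAgent(id=i, kind=kind, position=p, radius=r_cell))
    return cells


def write_observations(obs: TimecourseObservations, path) -> None:
    """Write observations as a delimited table: gene, time_h, value."""
    rows = []
    for gene in obs.values.index:
        for t in obs.values.columns:
            rows.append({"gene": gene, "time_h": float(t),
                         "value": obs.values.loc[gene, t]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_observations(path) -> pd.DataFrame:
    """Read a gene/time_h/value table into a genes x times frame."""
    table = pd.read_csv(path, sep="\t")
    frame = table.pivot(index="gene", columns="time_h", values="value")
    frame = frame[sorted(frame.columns)]
    return frame
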