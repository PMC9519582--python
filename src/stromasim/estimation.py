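"""Joint state/parameter estimation and sensitivity screening.

The estimator is a continuous-discrete unscented Kalman filter: between
sparse measurement times the sigma points are propagated through the full
nonlinear ODE system (continuous dynamics), and at each measurement time a
standard unscented correction is applied (discrete measurements).  Unknown
kinetic parameters are estimated jointly with the state by augmenting the
state vector with the parameters on log scale, which keeps every estimate
strictly positive, and giving them random-walk process noise.  Because the
data are short time courses, the filter is iterated: each pass re-starts
the states from their initial condition while carrying the parameter
statistics forward.

Morris elementary-effects screening and the agreement statistics
(goodness of fit, Bland-Altman limits of agreement) used to validate
fitted models against measured fold changes live here too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .cell_models import CellModelSpec
from .reaction_network import SolverError, assemble_rhs, simulate_network

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterState",
    "EstimationResult",
    "MorrisResult",
    "sigma_points",
    "hukf_estimate",
    "goodness_of_fit",
    "bland_altman",
    "morris_screening",
]

#: eigenvalue floor used when re-imposing positive semidefiniteness
PSD_FLOOR = 1e-12


@dataclass
class FilterConfig:
    """Unscented-transform scalars, noise scales and iteration control."""

    alpha: float = 1e-3
    beta: float = 2.0
    kappa: float = 0.0
    process_noise_state: float = 1e-6
    process_noise_param: float = 1e-4
    measurement_noise: float = 2.5e-3
    init_state_var: float = 1e-2
    init_param_var: float = 0.25
    n_passes: int = 10
    free_parameters: list[str] = field(default_factory=list)
    fold_change: bool = True  # measure observables as fold change over t=0
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        for attr in ("process_noise_state", "process_noise_param", "measurement_noise"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")


@dataclass
class FilterState:
    """Augmented mean (states ++ log-parameters) and covariance."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        asym = np.max(np.abs(self.covariance - self.covariance.T))
        if asym > 1e-10:
            raise ValueError(f"covariance asymmetric by {asym:g}")


@dataclass
class EstimationResult:
    estimated_parameters: dict[str, float]
    fitted_trajectory: object
    fit_statistics: pd.DataFrame
    filtered_means: np.ndarray          # (n_times, n_states) from the last pass
    parameter_history: np.ndarray       # (n_passes, n_free) after each pass


@dataclass
class MorrisResult:
    parameters: list[str]
    mu: np.ndarray
    mu_star: np.ndarray
    sigma: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mu": self.mu, "mu_star": self.mu_star, "sigma": self.sigma},
            index=self.parameters,
        )


def sigma_points(
    mean: np.ndarray, covariance: np.ndarray, cfg: FilterConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled unscented transform: 2n+1 points and mean/cov weight vectors.

    The weighted mean of the points reproduces ``mean`` exactly and the
    weighted covariance reproduces ``covariance`` to floating precision.
    """
    cfg = cfg or FilterConfig()
    mean = np.asarray(mean, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    n = mean.size
    lam = cfg.alpha**2 * (n + cfg.kappa) - n
    scaled = (n + lam) * covariance
    try:
        root = linalg.cholesky(scaled, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"covariance not positive definite: {exc}")
    points = np.empty((2 * n + 1, n))
    points[0] = mean
    for i in range(n):
        points[1 + i] = mean + root[:, i]
        points[1 + n + i] = mean - root[:, i]
    wm = np.full(2 * n + 1, 1.0 / (2 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = wm[0] + (1 - cfg.alpha**2 + cfg.beta)
    return points, wm, wc


def _force_psd(P: np.ndarray) -> np.ndarray:
    """Symmetrize and floor eigenvalues so the covariance stays PSD."""
    P = 0.5 * (P + P.T)
    vals, vecs = np.linalg.eigh(P)
    if vals.min() < PSD_FLOOR:
        vals = np.maximum(vals, PSD_FLOOR)
        P = (vecs * vals) @ vecs.T
        P = 0.5 * (P + P.T)
    return P


class ContinuousDiscreteUKF:
    """UKF with user-supplied continuous propagation and measurement maps.

    ``propagate(point, t0, t1) -> point`` integrates one augmented sigma
    point over an inter-sample interval; ``measure(point) -> y`` maps a
    point to observation space.
    """

    def __init__(self, propagate, measure, n_obs: int, cfg: FilterConfig,
                 Q: np.ndarray, R: np.ndarray):
        self.propagate = propagate
        self.measure = measure
        self.n_obs = n_obs
        self.cfg = cfg
        self.Q = Q
        self.R = R

    def step(self, state: FilterState, t0: float, t1: float,
             y: np.ndarray) -> FilterState:
        pts, wm, wc = sigma_points(state.mean, state.covariance, self.cfg)
        prop = np.empty_like(pts)
        n_failed = 0
        for i, p in enumerate(pts):
            try:
                prop[i] = self.propagate(p, t0, t1)
            except SolverError:
                n_failed += 1
                prop[i] = state.mean
        if n_failed:
            logger.warning("%d/%d sigma points failed to integrate on [%g, %g]",
                           n_failed, len(pts), t0, t1)
            if n_failed == len(pts):
                raise RuntimeError(f"all sigma points failed on [{t0}, {t1}]")
        m_pred = wm @ prop
        d = prop - m_pred
        P_pred = _force_psd((d.T * wc) @ d + self.Q)

        pts2, wm2, wc2 = sigma_points(m_pred, P_pred, self.cfg)
        ys = np.array([self.measure(p) for p in pts2])
        y_pred = wm2 @ ys
        dy = ys - y_pred
        dx = pts2 - m_pred
        S = (dy.T * wc2) @ dy + self.R
        C = (dx.T * wc2) @ dy
        K = np.linalg.solve(S.T, C.T).T
        mean = m_pred + K @ (y - y_pred)
        cov = _force_psd(P_pred - K @ S @ K.T)
        return FilterState(mean, cov)


def hukf_estimate(
    spec: CellModelSpec,
    observations: pd.DataFrame,
    cfg: FilterConfig,
    initial_parameters: dict[str, float] | None = None,
    inputs: dict[str, float] | None = None,
) -> EstimationResult:
    """Estimate free kinetic parameters of a cell model from a time course.

    ``observations`` is a genes x times frame of fold changes (columns are
    times in hours, including t=0).  Returns exponentiated parameter means
    after ``cfg.n_passes`` iterated filter passes plus the trajectory of
    the re-fitted model and per-gene fit statistics.
    """
    net = spec.network
    times = np.array(sorted(float(c) for c in observations.columns))
    if times.size < 2 or times[0] != 0.0:
        raise ValueError("observations must cover >= 2 times including t=0")
    genes = [g for g in spec.observable_map if g in observations.index]
    if not genes:
        raise ValueError("no mapped genes found in observations")
    unknown = [p for p in cfg.free_parameters if p not in net.parameters]
    if unknown:
        raise KeyError(f"free parameters not in network: {unknown}")

    dyn = net.dynamical_species
    obs_idx = np.array([dyn.index(spec.observable_map[g]) for g in genes])
    n_x, n_p = len(dyn), len(cfg.free_parameters)
    n_aug = n_x + n_p
    x0 = net.initial_state()
    baseline = x0[obs_idx].copy()
    if cfg.fold_change and np.any(baseline <= 0):
        raise ZeroDivisionError("zero baseline for a mapped observable")

    params_full = dict(net.parameters)
    if initial_parameters:
        params_full.update(initial_parameters)
    theta0 = np.array([params_full[p] for p in cfg.free_parameters])
    u = spec.input_vector(inputs)
    rhs = assemble_rhs(net)

    def propagate(point, t0, t1):
        x = np.maximum(point[:n_x], 0.0)
        if n_p:
            pd_ = dict(params_full)
            pd_.update(zip(cfg.free_parameters, np.exp(point[n_x:])))
        else:
            pd_ = params_full
        traj = simulate_network(net, x, parameters=pd_, inputs=u,
                                times=(t0, t1), rtol=cfg.ode_rtol, atol=cfg.ode_atol)
        out = point.copy()
        out[:n_x] = traj.values[-1]
        return out  # log-parameters follow a random walk: unchanged

    def measure(point):
        vals = point[obs_idx]
        return vals / baseline if cfg.fold_change else vals

    Q = np.diag(np.concatenate([
        np.full(n_x, cfg.process_noise_state),
        np.full(n_p, cfg.process_noise_param),
    ]))
    R = cfg.measurement_noise * np.eye(len(genes))
    ukf = ContinuousDiscreteUKF(propagate, measure, len(genes), cfg, Q, R)

    y_by_time = {t: observations.loc[genes, t].to_numpy(dtype=float) for t in times}
    log_theta = np.log(theta0) if n_p else np.zeros(0)
    P_param = cfg.init_param_var * np.eye(n_p)
    history = np.empty((cfg.n_passes, n_p))
    filtered = None

    for ipass in range(cfg.n_passes):
        mean = np.concatenate([x0, log_theta])
        cov = np.zeros((n_aug, n_aug))
        cov[:n_x, :n_x] = cfg.init_state_var * np.eye(n_x)
        cov[n_x:, n_x:] = P_param
        state = FilterState(mean, cov)
        filtered = [state.mean[:n_x].copy()]
        for t0, t1 in zip(times[:-1], times[1:]):
            state = ukf.step(state, t0, t1, y_by_time[t1])
            filtered.append(state.mean[:n_x].copy())
        log_theta = state.mean[n_x:].copy()
        P_param = state.covariance[n_x:, n_x:].copy()
        history[ipass] = np.exp(log_theta)

    estimates = dict(zip(cfg.free_parameters, np.exp(log_theta)))
    params_fit = dict(params_full)
    params_fit.update(estimates)
    fitted = simulate_network(net, x0, parameters=params_fit, inputs=u, times=times)
    stats = {}
    for gi, g in enumerate(genes):
        pred = fitted.values[:, obs_idx[gi]]
        if cfg.fold_change:
            pred = pred / baseline[gi]
        obs = np.array([y_by_time[t][gi] for t in times])
        stats[g] = goodness_of_fit(pred, obs)
    return EstimationResult(
        estimated_parameters=estimates,
        fitted_trajectory=fitted,
        fit_statistics=pd.DataFrame(stats).T,
        filtered_means=np.array(filtered),
        parameter_history=history,
    )


def goodness_of_fit(predicted, observed) -> dict[str, float]:
    """R^2 = 1 - SSres/SStot, plus RMSE and MAE."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 2:
        raise ValueError("predicted and observed must have equal length >= 2")
    resid = observed - predicted
    sstot = np.sum((observed - observed.mean()) ** 2)
    if sstot == 0:
        raise ZeroDivisionError("observed values have zero variance: R^2 undefined")
    return {
        "R2": 1.0 - np.sum(resid**2) / sstot,
        "RMSE": float(np.sqrt(np.mean(resid**2))),
        "MAE": float(np.mean(np.abs(resid))),
    }


def bland_altman(a, b) -> dict[str, float]:
    """Bias and 1.96-sd limits of agreement between two measurement sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}


def morris_screening(
    model_fn,
    ranges: dict[str, tuple[float, float]],
    r: int = 10,
    delta: float = 0.5,
    seed: int | None = None,
    levels: int = 4,
) -> MorrisResult:
    """Morris one-at-a-time elementary-effects screening.

    ``model_fn`` maps a parameter dict to a scalar output.  Each of the
    ``r`` trajectories draws a base point on a ``levels``-level grid of the
    unit hypercube, then perturbs one parameter at a time by ``delta``
    (fraction of its range, in random order).  The elementary effect of
    parameter i is ``(y(theta + D e_i) - y(theta)) / D`` with ``D`` the step
    in physical units; mu/mu_star/sigma are its mean, mean magnitude and
    standard deviation over trajectories.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if not (0 < delta < 1):
        raise ValueError("delta must be in (0, 1)")
    rng = np.random.default_rng(seed)
    names = list(ranges)
    lo = np.array([ranges[n][0] for n in names], dtype=float)
    hi = np.array([ranges[n][1] for n in names], dtype=float)
    span = hi - lo
    k = len(names)
    grid = np.linspace(0.0, 1.0 - delta, levels)

    effects: list[np.ndarray] = []
    for _ in range(r):
        unit = rng.choice(grid, size=k)
        theta = lo + unit * span
        ee = np.full(k, np.nan)
        y0 = model_fn(dict(zip(names, theta)))
        ok = np.isfinite(y0)
        for i in rng.permutation(k):
            step = delta * span[i]
            theta_next = theta.copy()
            theta_next[i] = theta[i] + step
            y1 = model_fn(dict(zip(names, theta_next)))
            if not (np.isfinite(y1) and ok):
                ok = False
                break
            ee[i] = (y1 - y0) / step
            theta, y0 = theta_next, y1
        if ok and np.all(np.isfinite(ee)):
            effects.append(ee)
        else:
            warnings.warn("Morris trajectory dropped: model output not finite")
    if not effects:
        raise RuntimeError("all Morris trajectories produced non-finite output")
    E = np.array(effects)
    mu = E.mean(axis=0)
    mu_star = np.abs(E).mean(axis=0)
    sigma = E.std(axis=0, ddof=1) if len(effects) > 1 else np.zeros(k)
    return MorrisResult(parameters=names, mu=mu, mu_star=mu_star, sigma=sigma)
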