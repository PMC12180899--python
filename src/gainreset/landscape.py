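"""Energy-landscape analyses of low-dimensional network trajectories.

Probability and energy are linked through the Boltzmann relation
``p = exp(-beta E) / Z``; with the density estimated directly from data
(a Gaussian kernel density, which integrates to 1, so Z = 1) and
``beta = 1``, the energy of a state is its surprisal ``E = ln(1 / p)``.

Two complementary landscapes are computed:

- *allocentric*: the state is the position of the trajectory on the
  leading principal component of the network's firing rates, binned into
  time windows (default 250 ms); the landscape E(window, position) plays
  the role of a time-resolved potential, and "neural work"
  ``W_t = -(dE/dx) * s_t`` measures the force it exerts on the
  trajectory over each window.
- *egocentric*: the state is the mean-squared displacement (MSD) of unit
  activity between lagged time points, irrespective of position; the
  landscape E(MSD) measures how surprising displacements of a given size
  are, and its area under the curve summarises how much energy large
  movements require.

The kernel density uses a normalised Gaussian kernel with Silverman's
bandwidth rule by default (bandwidth exposed in config).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .rnn import TrainedNetwork, TrialRecord, simulate_trial
from .task import generate_morph_input

__all__ = [
    "LowDimProjection",
    "EnergyConfig",
    "EnergyLandscape",
    "WorkSeries",
    "fit_pca_rnn",
    "project_and_velocity",
    "kde_energy",
    "allocentric_landscape",
    "neural_work",
    "msd",
    "egocentric_landscape",
    "simulate_gamma_ensemble",
]


@dataclass
class LowDimProjection:
    """PCA loadings and variance explained for one network's activity."""

    loadings: np.ndarray  # (n_units, k)
    variance_explained: np.ndarray  # (k,), percent
    mean_: np.ndarray  # (n_units,)

    def project(self, rates: np.ndarray, component: int = 0) -> np.ndarray:
        """Scores of (T, n_units) rates on one component."""
        return (rates - self.mean_) @ self.loadings[:, component]


@dataclass
class EnergyConfig:
    """Parameters of the energy estimation.

    ``thermo_beta`` and ``partition_z`` are fixed at 1 by the derivation
    (the KDE integrates to 1); they are carried for completeness.
    ``e_max`` caps the energy where the estimated density underflows to
    zero; display clipping (energies shown as > 6) is a plotting
    concern and does not alter stored values.
    """

    window_ms: float = 250.0
    thermo_beta: float = 1.0
    partition_z: float = 1.0
    kde_bandwidth: str | float = "silverman"
    n_grid: int = 101
    e_max: float = 50.0
    min_samples: int = 10


@dataclass
class EnergyLandscape:
    """Energy surface over (axis1 = window/lag, axis2 = position/MSD)."""

    axis1: np.ndarray
    axis2: np.ndarray  # evaluation grid of the state variable
    energy: np.ndarray  # (len(axis1), len(axis2))
    counts: np.ndarray  # samples per axis1 bin
    flagged: np.ndarray  # axis1 bins with too few samples


@dataclass
class WorkSeries:
    """Per-window displacement, energy gradient and neural work."""

    window_start_ms: np.ndarray
    displacement: np.ndarray  # s_t, absolute PC displacement per window
    gradient: np.ndarray  # dE/dx between window start and end positions
    work: np.ndarray  # W_t = -(dE/dx) * s_t


def fit_pca_rnn(rate_blocks: Sequence[np.ndarray], k: Optional[int] = None) -> LowDimProjection:
    """PCA of concatenated (T, n_units) firing-rate blocks.

    The blocks (trials of both directions, at gamma = 0) are stacked in
    time; components are unit-norm loadings over units and the variance
    explained is returned in percent.
    """
    from sklearn.decomposition import PCA

    data = np.vstack(rate_blocks)
    if np.linalg.matrix_rank(data - data.mean(axis=0)) < 1:
        raise ValueError("rate matrix is rank deficient (constant input)")
    k = min(data.shape) if k is None else k
    pca = PCA(n_components=k)
    pca.fit(data)
    return LowDimProjection(
        loadings=pca.components_.T,
        variance_explained=100.0 * pca.explained_variance_ratio_,
        mean_=pca.mean_,
    )


def project_and_velocity(
    record: TrialRecord, projection: LowDimProjection
) -> tuple[np.ndarray, np.ndarray]:
    """PC1 trajectory of a trial and its absolute velocity (per ms)."""
    traj = projection.project(record.r)
    dt = float(record.t_ms[1] - record.t_ms[0]) if len(record.t_ms) > 1 else 1.0
    vel = np.abs(np.diff(traj)) / dt
    return traj, vel


def velocity_peak(
    velocity: np.ndarray,
    t_ms: np.ndarray,
    settle_ms: float = 100.0,
) -> tuple[float, float]:
    """Time and magnitude of the velocity peak, ignoring the start transient.

    Trials start from the reset state x = 0; the relaxation away from it
    during the first ``settle_ms`` is not task dynamics and is excluded
    before locating the peak.
    """
    dt = float(t_ms[1] - t_ms[0])
    skip = round(settle_ms / dt)
    idx = skip + int(np.argmax(velocity[skip:]))
    return float(t_ms[idx]), float(velocity[idx])


def kde_energy(
    samples: np.ndarray,
    eval_grid: np.ndarray,
    config: Optional[EnergyConfig] = None,
) -> np.ndarray:
    """Surprisal E = ln(1/p_hat) from a Gaussian KDE of the samples.

    Zero (underflowing) densities are capped at ``config.e_max``.  With
    beta = Z = 1 the energy is exactly the negative log density, so
    exp(-E) integrates to ~1 over a grid covering the support.
    """
    config = config or EnergyConfig()
    samples = np.asarray(samples, dtype=float).ravel()
    if len(samples) < config.min_samples:
        raise ValueError(
            f"need at least {config.min_samples} samples, got {len(samples)}"
        )
    if np.ptp(samples) == 0.0:
        # degenerate sample set: point mass at the unique value
        e = np.full(len(eval_grid), config.e_max)
        e[np.argmin(np.abs(eval_grid - samples[0]))] = 0.0
        return e
    kde = gaussian_kde(samples, bw_method=config.kde_bandwidth)
    p = kde(np.asarray(eval_grid, dtype=float))
    with np.errstate(divide="ignore"):
        e = -np.log(p)
    return np.minimum(e, config.e_max)


def allocentric_landscape(
    trajectories: Sequence[np.ndarray],
    t_ms: np.ndarray,
    config: Optional[EnergyConfig] = None,
    eval_grid: Optional[np.ndarray] = None,
) -> EnergyLandscape:
    """Time-resolved energy over PC1 position.

    PC1 trajectories (one per trial, common time grid) are cut into
    ``window_ms`` windows; within each window the samples are pooled
    across trials and time steps, and the energy is estimated on a grid
    shared across windows.  Pooling is order-free, so the landscape is
    invariant to trial ordering.
    """
    config = config or EnergyConfig()
    trajs = np.asarray(trajectories, dtype=float)
    dt = float(t_ms[1] - t_ms[0])
    steps_per_win = round(config.window_ms / dt)
    n_windows = trajs.shape[1] // steps_per_win
    if eval_grid is None:
        lo, hi = trajs.min(), trajs.max()
        pad = 0.05 * (hi - lo + 1e-12)
        eval_grid = np.linspace(lo - pad, hi + pad, config.n_grid)
    energy = np.empty((n_windows, len(eval_grid)))
    counts = np.empty(n_windows, dtype=int)
    flagged = np.zeros(n_windows, dtype=bool)
    for w in range(n_windows):
        block = trajs[:, w * steps_per_win : (w + 1) * steps_per_win].ravel()
        counts[w] = block.size
        if block.size < config.min_samples:
            flagged[w] = True
            energy[w] = np.nan
            continue
        energy[w] = kde_energy(block, eval_grid, config)
    window_starts = np.arange(n_windows) * config.window_ms
    return EnergyLandscape(window_starts, np.asarray(eval_grid), energy, counts, flagged)


def neural_work(
    trajectory: np.ndarray,
    t_ms: np.ndarray,
    landscape: EnergyLandscape,
    config: Optional[EnergyConfig] = None,
) -> WorkSeries:
    """Neural work W_t = -(dE/dx) * s_t per landscape window.

    ``s_t`` is the absolute PC1 displacement across the window and the
    gradient is the finite difference of the window's energy between the
    end and start positions.  Zero displacement gives zero gradient and
    zero work.
    """
    config = config or EnergyConfig()
    dt = float(t_ms[1] - t_ms[0])
    steps_per_win = round(config.window_ms / dt)
    n_windows = len(landscape.axis1)
    disp = np.zeros(n_windows)
    grad = np.zeros(n_windows)
    work = np.zeros(n_windows)
    for w in range(n_windows):
        i0 = w * steps_per_win
        i1 = min(i0 + steps_per_win, len(trajectory) - 1)
        x0, x1 = trajectory[i0], trajectory[i1]
        disp[w] = abs(x1 - x0)
        if x1 == x0 or landscape.flagged[w]:
            continue
        e0 = np.interp(x0, landscape.axis2, landscape.energy[w])
        e1 = np.interp(x1, landscape.axis2, landscape.energy[w])
        grad[w] = (e1 - e0) / (x1 - x0)
        work[w] = -grad[w] * disp[w]
    return WorkSeries(landscape.axis1.copy(), disp, grad, work)


def msd(
    rates: np.ndarray,
    t_ms: np.ndarray,
    lag_step_ms: float = 250.0,
    max_lag_ms: float = 5000.0,
    start_ms: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-squared displacement of unit activity at lagged time points.

    ``MSD(tau0, tau) = < |r(tau0 + tau) - r(tau0)|^2 >_units`` with both
    the reference point tau0 and the lag tau advancing in
    ``lag_step_ms`` steps, tau0 starting at ``start_ms``.  Returns the
    lag of each sample and the MSD values; (tau0, tau) pairs that run
    past the series are skipped.
    """
    dt = float(t_ms[1] - t_ms[0])
    step = round(lag_step_ms / dt)
    start = round(start_ms / dt)
    T = rates.shape[0]
    lags: list[float] = []
    vals: list[float] = []
    max_lag_steps = round(max_lag_ms / dt)
    for tau0 in range(start, T, step):
        for tau in range(step, max_lag_steps + 1, step):
            if tau0 + tau >= T:
                break
            d = rates[tau0 + tau] - rates[tau0]
            lags.append(tau * dt)
            vals.append(float(np.mean(d * d)))
    return np.asarray(lags), np.asarray(vals)


def egocentric_landscape(
    msd_samples: dict[float, np.ndarray],
    config: Optional[EnergyConfig] = None,
    eval_grid: Optional[np.ndarray] = None,
) -> tuple[dict[float, np.ndarray], np.ndarray, dict[float, float]]:
    """Energy over MSD value per condition, plus its area under the curve.

    ``msd_samples`` maps a condition label (e.g. a gamma value) to its
    pooled MSD samples.  Energies are evaluated on a grid common to all
    conditions (spanning the union of their supports, so AUCs are
    comparable); the AUC is the trapezoidal integral of the energy over
    that grid.  Conditions whose samples never visit part of the common
    grid simply show capped (high) energy there, which is the point: a
    condition that makes large displacements likely has lower energy at
    large MSD.
    """
    config = config or EnergyConfig()
    if eval_grid is None:
        all_samples = np.concatenate([np.ravel(v) for v in msd_samples.values()])
        lo, hi = all_samples.min(), all_samples.max()
        pad = 0.05 * (hi - lo + 1e-12)
        eval_grid = np.linspace(max(0.0, lo - pad), hi + pad, config.n_grid)
    energies: dict[float, np.ndarray] = {}
    aucs: dict[float, float] = {}
    for key, samples in msd_samples.items():
        e = kde_energy(np.ravel(samples), eval_grid, config)
        energies[key] = e
        aucs[key] = float(np.trapezoid(e, eval_grid))
    return energies, np.asarray(eval_grid), aucs


def simulate_gamma_ensemble(
    network: TrainedNetwork,
    gammas: Sequence[float],
    extended_ms: float = 0.0,
    sigma_rec: float = 0.01,
    seed: int = 0,
    n_trials_per_direction: int = 1,
) -> dict[float, list[TrialRecord]]:
    """Task trials (both directions) at each gamma, optionally extended.

    With ``extended_ms > 0`` the input is held at its final value after
    the morph ends, giving the longer series the displacement analysis
    needs for lags beyond the trial length.
    """
    cfg = network.config
    out: dict[float, list[TrialRecord]] = {}
    ss = np.random.SeedSequence(seed)
    for gi, gamma in enumerate(gammas):
        recs = []
        for direction in (1, -1):
            trial = generate_morph_input(cfg.trial_duration_ms, cfg.dt_sim_ms, direction)
            u = trial.u
            if extended_ms > 0:
                n_extra = round(extended_ms / cfg.dt_sim_ms)
                u = np.vstack([u, np.tile(u[-1], (n_extra, 1))])
            for rep in range(n_trials_per_direction):
                s = int(
                    np.random.SeedSequence(
                        [ss.entropy, gi, direction % 3, rep]
                    ).generate_state(1)[0]
                    % (2**31)
                )
                recs.append(
                    simulate_trial(network, u, gamma=gamma, seed=s, sigma_rec=sigma_rec)
                )
        out[float(gamma)] = recs
    return out
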