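"""Dynamical-regime mapping over the (gain x input-ambiguity) plane.

For each combination of static gain and input mismatch
``delta_input = u1 - u2`` (with u1 + u2 = 1), many noise-free simulations
are run from random initial firing rates and classified by whether the
summed absolute rate change per step falls (and stays) below a tolerance
within the horizon.  The proportion of converged initialisations proxies
the presence of a fixed-point attractor; the time to convergence proxies
its strength.  Near delta_input = 0 at high gain the dynamics instead
enter sustained high-amplitude oscillations.

The convergence statistic uses the *sum of absolute* rate differences
Delta_r = sum_i |r_i(t) - r_i(t - dt)|; a signed sum can cancel to zero
mid-oscillation and would not indicate convergence.  A run counts as
converged only once Delta_r stays below tolerance for a full dwell
window (default 100 ms), which rejects spurious zero-crossings of the
oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .rnn import TrainedNetwork, effective_weights, inverse_activation

__all__ = ["ConvergenceResult", "RegimeGrid", "convergence_run", "regime_grid"]


@dataclass
class ConvergenceResult:
    """Outcome of one (gain, delta_input) cell."""

    proportion: float
    mean_time_ms: float  # over converged runs only (nan if none)
    mean_time_all_ms: float  # non-converged runs count the full horizon
    times_ms: np.ndarray  # per-run convergence time; nan where not converged
    osc_variance: float  # mean over units/runs of rate variance in the final window


@dataclass
class RegimeGrid:
    """Convergence maps over the (gain x delta_input) plane."""

    gain_values: np.ndarray
    delta_values: np.ndarray
    convergence_proportion: np.ndarray  # (n_gain, n_delta)
    convergence_time_ms: np.ndarray  # (n_gain, n_delta); nan where nothing converged
    osc_variance: np.ndarray  # (n_gain, n_delta)
    n_init: int
    horizon_ms: float
    tolerance: float

    def nonconverging_band_width(self, prop_threshold: float = 0.5) -> np.ndarray:
        """Width (in delta_input units) of the band with proportion < threshold."""
        below = self.convergence_proportion < prop_threshold
        if len(self.delta_values) > 1:
            d_step = float(np.mean(np.diff(self.delta_values)))
        else:
            d_step = 1.0
        return below.sum(axis=1) * d_step

    def to_frame(self):
        import pandas as pd

        g, d = np.meshgrid(self.gain_values, self.delta_values, indexing="ij")
        return pd.DataFrame(
            {
                "gain": g.ravel(),
                "delta_input": d.ravel(),
                "convergence_proportion": self.convergence_proportion.ravel(),
                "convergence_time_ms": self.convergence_time_ms.ravel(),
                "osc_variance": self.osc_variance.ravel(),
            }
        )


def convergence_run(
    network: TrainedNetwork,
    gain: float,
    delta_input: float,
    n_init: int = 100,
    horizon_ms: float = 10_000.0,
    tolerance: float = 1e-2,
    seed: Optional[int] = None,
    dwell_ms: float = 100.0,
    final_window_ms: float = 2000.0,
) -> ConvergenceResult:
    """Noise-free convergence statistics for one parameter-plane cell.

    Initial firing rates are uniform on [0, 1] (subthreshold states via
    the inverse sigmoid at the applied gain); all ``n_init``
    initialisations are integrated together as one batched linear-algebra
    loop.  The run ends early once every initialisation has converged.
    ``osc_variance`` is the mean temporal variance of the rates over the
    final ``final_window_ms`` of the horizon (0 when every run converged
    before that window started).
    """
    cfg = network.config
    w_rec, w_in, _ = effective_weights(network.weights)
    dt = cfg.dt_sim_ms
    a = dt / cfg.tau_ms
    n = cfg.n_total
    rng = np.random.default_rng(seed)

    u = np.array([(1.0 + delta_input) / 2.0, (1.0 - delta_input) / 2.0])
    input_drive = (w_in @ u)[:, None]  # constant per unit

    r = rng.uniform(0.0, 1.0, (n, n_init))
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    x = inverse_activation(r, gain)

    n_steps = round(horizon_ms / dt)
    dwell_steps = max(1, round(dwell_ms / dt))
    final_start = n_steps - round(final_window_ms / dt)

    below_count = np.zeros(n_init, dtype=int)
    conv_step = np.full(n_init, -1, dtype=int)
    var_sum = np.zeros((n, n_init))
    var_sumsq = np.zeros((n, n_init))
    var_n = 0

    r_prev = r
    for step in range(1, n_steps + 1):
        x = (1.0 - a) * x + a * (w_rec @ r_prev + input_drive)
        r = 1.0 / (1.0 + np.exp(-gain * x))
        delta_r = np.abs(r - r_prev).sum(axis=0)
        below = delta_r < tolerance
        below_count = np.where(below, below_count + 1, 0)
        newly = (below_count == dwell_steps) & (conv_step < 0)
        if newly.any():
            # convergence dated at the start of the dwell window
            conv_step[newly] = step - dwell_steps + 1
        if step >= final_start:
            var_sum += r
            var_sumsq += r * r
            var_n += 1
        if step < final_start and (conv_step >= 0).all():
            break
        r_prev = r

    converged = conv_step >= 0
    times = np.where(converged, conv_step * dt, np.nan)
    prop = float(converged.mean())
    mean_time = float(np.nanmean(times)) if converged.any() else float("nan")
    mean_all = float(np.where(converged, conv_step * dt, horizon_ms).mean())
    # oscillation amplitude: temporal rate variance over the final window,
    # averaged over units, for runs that never converged (0 if all did)
    if var_n > 1 and (~converged).any():
        mean = var_sum[:, ~converged] / var_n
        per_unit = var_sumsq[:, ~converged] / var_n - mean * mean
        osc_var = float(per_unit.mean())
    else:
        osc_var = 0.0
    return ConvergenceResult(prop, mean_time, mean_all, times, osc_var)


def regime_grid(
    network: TrainedNetwork,
    gain_range: tuple[float, float] = (0.5, 1.5),
    delta_range: tuple[float, float] = (-1.0, 1.0),
    resolution: tuple[int, int] = (21, 21),
    n_init: int = 100,
    horizon_ms: float = 10_000.0,
    tolerance: float = 1e-2,
    seed: Optional[int] = None,
    dwell_ms: float = 100.0,
) -> RegimeGrid:
    """Convergence proportion/time over the full parameter plane."""
    if resolution[0] < 3 or resolution[1] < 3:
        raise ValueError("resolution must be >= 3 per axis")
    gains = np.linspace(*gain_range, resolution[0])
    deltas = np.linspace(*delta_range, resolution[1])
    prop = np.empty((len(gains), len(deltas)))
    tmean = np.empty_like(prop)
    osc = np.empty_like(prop)
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(prop.size).reshape(prop.shape)
    for i, g in enumerate(gains):
        for j, d in enumerate(deltas):
            res = convergence_run(
                network,
                g,
                d,
                n_init=n_init,
                horizon_ms=horizon_ms,
                tolerance=tolerance,
                seed=int(cell_seeds[i, j]),
                dwell_ms=dwell_ms,
            )
            prop[i, j] = res.proportion
            tmean[i, j] = res.mean_time_ms
            osc[i, j] = res.osc_variance
    return RegimeGrid(gains, deltas, prop, tmean, osc, n_init, horizon_ms, tolerance)
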