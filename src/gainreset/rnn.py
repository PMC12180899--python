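"""Continuous-time Dale's-law E/I recurrent network with dynamic gain.

The network integrates

    tau dx/dt = -x + W_rec r + W_in u + noise,      r = sigmoid(g * x)

with an Euler-Maruyama scheme, and the (uniform) gain ``g`` follows a
linear ODE forced by the Shannon entropy of the softmaxed readout:

    tau dg/dt = g_tonic - g + gamma * H(z)

so that gain rises phasically whenever the readout is uncertain and decays
back to its tonic value otherwise.  Dale's law is imposed by parametrising
the recurrent weights as ``|W_plastic| * mask`` where the mask carries each
presynaptic unit's sign (+1 for excitatory, -1 for inhibitory columns) and
zeros on the diagonal; input and readout weights are constrained positive
by taking absolute values.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "RNNConfig",
    "NetworkWeights",
    "NetworkState",
    "TrialRecord",
    "TrainedNetwork",
    "build_dale_mask",
    "effective_weights",
    "activation",
    "inverse_activation",
    "readout_probs",
    "softmax",
    "entropy",
    "gain_step",
    "euler_step",
    "simulate_trial",
    "save_network",
    "load_network",
    "trial_record_to_frame",
]

ARCHIVE_SCHEMA_VERSION = 1


class NumericalInstabilityError(RuntimeError):
    """Raised when the simulated state becomes non-finite."""


@dataclass(frozen=True)
class RNNConfig:
    """Hyperparameters of the E/I network and its simulation.

    Attributes
    ----------
    n_exc, n_inh : int
        Sizes of the excitatory and inhibitory populations (default 32/8,
        an 80/20 ratio).
    tau_ms : float
        Membrane/gain time constant in milliseconds.
    dt_sim_ms : float
        Integration step used for analysis simulations (1 ms).
    dt_train_ms : float
        Coarser step used during training (default 100 ms, i.e. alpha =
        dt/tau = 1).  Steps with alpha > 1 are accepted and applied
        exactly as written but trigger a warning: the one-step training
        map is then non-contractive and trained solutions fail to
        transfer to the fine-step dynamics.
    sigma_rec : float
        Scale of the per-unit Wiener increments; each step adds
        ``sigma_rec * sqrt(dt_ms) * N(0,1)``.
    g_tonic : float
        Tonic (baseline) gain the dynamic gain decays to.
    gamma : float
        Magnitude of the entropy forcing on gain.
    omega : float
        Inverse temperature of the readout softmax used for the
        uncertainty signal (0.25).
    trial_duration_ms : float
        Task trial length (1000 ms of simulation time).
    """

    n_exc: int = 32
    n_inh: int = 8
    tau_ms: float = 100.0
    dt_sim_ms: float = 1.0
    dt_train_ms: float = 100.0
    sigma_rec: float = 0.01
    g_tonic: float = 1.0
    gamma: float = 0.0
    omega: float = 0.25
    trial_duration_ms: float = 1000.0

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    def __post_init__(self) -> None:
        if self.n_exc < 1 or self.n_inh < 1:
            raise ValueError("population sizes must be positive")
        if self.tau_ms <= 0 or self.dt_sim_ms <= 0 or self.dt_train_ms <= 0:
            raise ValueError("time constants and steps must be positive")
        if self.sigma_rec < 0:
            raise ValueError("sigma_rec must be nonnegative")
        if self.trial_duration_ms <= 0:
            raise ValueError("trial duration must be positive")


@dataclass
class NetworkWeights:
    """Unconstrained (plastic) weights plus the Dale sign mask.

    The effective weights seen by the dynamics are obtained through
    :func:`effective_weights`; the plastic matrices are what the optimiser
    updates, so the sign constraints can never be violated by training.
    """

    w_rec_plastic: np.ndarray  # (n, n)
    w_mask: np.ndarray  # (n, n), entries in {-1, 0, +1}
    w_in_plastic: np.ndarray  # (n, 2)
    w_out_plastic: np.ndarray  # (2, n_exc)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.w_rec_plastic.copy(),
            self.w_mask.copy(),
            self.w_in_plastic.copy(),
            self.w_out_plastic.copy(),
        )


@dataclass
class NetworkState:
    """Instantaneous state of the simulated network."""

    x: np.ndarray
    r: np.ndarray
    g: np.ndarray
    t_ms: float = 0.0


@dataclass
class TrialRecord:
    """Full per-time-step record of one simulated trial."""

    t_ms: np.ndarray  # (T,)
    u: np.ndarray  # (T, 2)
    x: np.ndarray  # (T, n)
    r: np.ndarray  # (T, n)
    g: np.ndarray  # (T,)  gain is uniform across units
    z: np.ndarray  # (T, 2)
    p: np.ndarray  # (T, 2)
    H: np.ndarray  # (T,)  nats
    choice: np.ndarray  # (T,)  argmax of z, in {0, 1}

    @property
    def n_steps(self) -> int:
        return len(self.t_ms)


@dataclass
class TrainedNetwork:
    """A network (config + weights) plus training metadata."""

    config: RNNConfig
    weights: NetworkWeights
    meta: dict = field(default_factory=dict)

    def copy(self) -> "TrainedNetwork":
        return TrainedNetwork(self.config, self.weights.copy(), dict(self.meta))


def build_dale_mask(n_exc: int, n_inh: int) -> np.ndarray:
    """Sign mask with zero diagonal and sign set by the presynaptic unit.

    Column ``j`` (presynaptic unit ``j`` in the update ``W_rec r``) is +1
    for the first ``n_exc`` units and -1 for the remaining ``n_inh``, so a
    unit's outgoing synapses share one sign, as Dale's law requires.
    """
    if n_exc < 1 or n_inh < 1:
        raise ValueError("n_exc and n_inh must be >= 1")
    n = n_exc + n_inh
    col_sign = np.ones(n)
    col_sign[n_exc:] = -1.0
    mask = np.tile(col_sign, (n, 1))
    np.fill_diagonal(mask, 0.0)
    return mask


def effective_weights(
    weights: NetworkWeights,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constrained weights: ``|W_rec| * mask``, ``|W_in|``, ``|W_out|``."""
    if weights.w_rec_plastic.shape != weights.w_mask.shape:
        raise ValueError("recurrent weights and mask shapes differ")
    w_rec = np.abs(weights.w_rec_plastic) * weights.w_mask
    w_in = np.abs(weights.w_in_plastic)
    w_out = np.abs(weights.w_out_plastic)
    return w_rec, w_in, w_out


def activation(x: np.ndarray, g: np.ndarray | float) -> np.ndarray:
    """Gain-modulated sigmoid rate, r = 1 / (1 + exp(-g * x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(g) * x))


def inverse_activation(r: np.ndarray, g: np.ndarray | float) -> np.ndarray:
    """Subthreshold activation producing rate ``r`` at gain ``g``."""
    r = np.asarray(r, dtype=float)
    return np.log(r / (1.0 - r)) / g


def softmax(z: np.ndarray, omega: float) -> np.ndarray:
    """Softmax with inverse temperature omega along the last axis."""
    w = omega * np.asarray(z, dtype=float)
    w = w - w.max(axis=-1, keepdims=True)
    e = np.exp(w)
    return e / e.sum(axis=-1, keepdims=True)


def entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in nats, H = -sum p ln p (0 ln 0 := 0)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


def readout_probs(
    r_exc: np.ndarray, w_out_eff: np.ndarray, omega: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Readout z = W_out r_E, softmax probabilities, and their entropy."""
    z = w_out_eff @ r_exc
    p = softmax(z, omega)
    return z, p, float(entropy(p))


def gain_step(
    g: np.ndarray | float, H: float, config: RNNConfig, dt_ms: float
) -> np.ndarray | float:
    """Forward-Euler step of tau dg/dt = g_tonic - g + gamma * H."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    a = dt_ms / config.tau_ms
    return g + a * (config.g_tonic - g + config.gamma * H)


def euler_step(
    x: np.ndarray,
    r: np.ndarray,
    u: np.ndarray,
    w_rec_eff: np.ndarray,
    w_in_eff: np.ndarray,
    config: RNNConfig,
    dt_ms: float,
    noise_draw: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One Euler-Maruyama step of the subthreshold dynamics.

    x(t + dt) = (1 - a) x + a (W_rec r + W_in u) + sigma_rec sqrt(dt) N(0,1)
    with a = dt / tau.  ``noise_draw`` holds the standard-normal draws (or
    ``None`` for a deterministic step).
    """
    a = dt_ms / config.tau_ms
    x_new = (1.0 - a) * x + a * (w_rec_eff @ r + w_in_eff @ u)
    if noise_draw is not None and config.sigma_rec > 0:
        x_new = x_new + config.sigma_rec * np.sqrt(dt_ms) * noise_draw
    return x_new


def simulate_trial(
    network: TrainedNetwork,
    input_series: np.ndarray,
    gamma: Optional[float] = None,
    seed: Optional[int] = None,
    static_gain: Optional[float] = None,
    sigma_rec: Optional[float] = None,
    dt_ms: Optional[float] = None,
    x0: Optional[np.ndarray] = None,
) -> TrialRecord:
    """Simulate one trial and record the full state trajectory.

    Parameters
    ----------
    input_series : (T, 2) array
        External input at each time step (one row per step, including t=0).
    gamma : float, optional
        Entropy-forcing magnitude; overrides the config value.  With
        ``gamma = 0`` gain stays at its tonic value.
    static_gain : float, optional
        If given, gain is frozen at this value for the whole trial and the
        gain ODE is skipped (the static-gain sweep mode).
    sigma_rec : float, optional
        Override the recurrent noise scale (0 gives a deterministic run).
    x0 : array, optional
        Initial subthreshold state (defaults to zeros).
    """
    cfg = network.config
    if gamma is not None:
        cfg = replace(cfg, gamma=gamma)
    if sigma_rec is not None:
        cfg = replace(cfg, sigma_rec=sigma_rec)
    dt = cfg.dt_sim_ms if dt_ms is None else dt_ms
    w_rec, w_in, w_out = effective_weights(network.weights)

    u = np.asarray(input_series, dtype=float)
    if u.ndim != 2 or u.shape[1] != 2:
        raise ValueError("input_series must have shape (T, 2)")
    T = u.shape[0]
    n = cfg.n_total

    rng = np.random.default_rng(seed)
    use_noise = cfg.sigma_rec > 0

    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    g = cfg.g_tonic if static_gain is None else float(static_gain)

    t_grid = np.arange(T) * dt
    X = np.empty((T, n))
    R = np.empty((T, n))
    G = np.empty(T)
    Z = np.empty((T, 2))
    P = np.empty((T, 2))
    Hs = np.empty(T)

    for t in range(T):
        r = activation(x, g)
        z, p, H = readout_probs(r[: cfg.n_exc], w_out, cfg.omega)
        X[t], R[t], G[t], Z[t], P[t], Hs[t] = x, r, g, z, p, H
        if t == T - 1:
            break
        noise = rng.standard_normal(n) if use_noise else None
        x = euler_step(x, r, u[t], w_rec, w_in, cfg, dt, noise)
        if not np.all(np.isfinite(x)):
            raise NumericalInstabilityError(
                f"non-finite state at step {t + 1} (t = {(t + 1) * dt:.1f} ms)"
            )
        if static_gain is None:
            g = gain_step(g, H, cfg, dt)

    choice = np.argmax(Z, axis=1)
    return TrialRecord(t_grid, u, X, R, G, Z, P, Hs, choice)


def trial_record_to_frame(record: TrialRecord):
    """Long-format table (time_ms, channel, variable, value) of a trial."""
    import pandas as pd

    rows = []
    for name, arr in [("x", record.x), ("r", record.r)]:
        T, n = arr.shape
        rows.append(
            pd.DataFrame(
                {
                    "time_ms": np.repeat(record.t_ms, n),
                    "channel": np.tile(np.arange(n), T),
                    "variable": name,
                    "value": arr.ravel(),
                }
            )
        )
    for name, arr in [("u", record.u), ("z", record.z), ("p", record.p)]:
        T, k = arr.shape
        rows.append(
            pd.DataFrame(
                {
                    "time_ms": np.repeat(record.t_ms, k),
                    "channel": np.tile(np.arange(k), T),
                    "variable": name,
                    "value": arr.ravel(),
                }
            )
        )
    for name, arr in [("g", record.g), ("H", record.H), ("choice", record.choice)]:
        rows.append(
            pd.DataFrame(
                {
                    "time_ms": record.t_ms,
                    "channel": 0,
                    "variable": name,
                    "value": np.asarray(arr, dtype=float),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def save_network(network: TrainedNetwork, path) -> None:
    """Write a self-describing network archive (.npz with a JSON header)."""
    header = json.dumps(
        {
            "schema_version": ARCHIVE_SCHEMA_VERSION,
            "config": asdict(network.config),
            "meta": {
                k: v
                for k, v in network.meta.items()
                if isinstance(v, (int, float, str, bool, list))
            },
        }
    )
    np.savez(
        path,
        header=np.frombuffer(header.encode(), dtype=np.uint8),
        w_rec_plastic=network.weights.w_rec_plastic,
        w_mask=network.weights.w_mask,
        w_in_plastic=network.weights.w_in_plastic,
        w_out_plastic=network.weights.w_out_plastic,
    )


def load_network(path) -> TrainedNetwork:
    """Read a network archive written by :func:`save_network`."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header.get("schema_version") != ARCHIVE_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported archive schema: {header.get('schema_version')}"
            )
        weights = NetworkWeights(
            data["w_rec_plastic"].copy(),
            data["w_mask"].copy(),
            data["w_in_plastic"].copy(),
            data["w_out_plastic"].copy(),
        )
    cfg = RNNConfig(**header["config"])
    return TrainedNetwork(cfg, weights, header.get("meta", {}))
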