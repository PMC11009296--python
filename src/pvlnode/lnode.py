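"""Latent neural-ODE surrogate of four-chamber pressure-volume dynamics.

The surrogate is the ODE system

    dz/dt = ANN(z, cos(2*pi*(t - AV_delay)/T_HB), sin(2*pi*(t - AV_delay)/T_HB), theta; w)

where ``z = [z_physical, z_latent]`` stacks the 8 scaled pressure/volume
states with ``n_latent`` dimensionless latent states, and ``theta`` is the
physical parameter vector scaled to ``[-1, 1]``.  Time enters the network
only through the two periodic clock features, which carry the heartbeat
period and atrioventricular delay.  The ANN is a small fully-connected
feedforward network (default 3 hidden layers of 13 tanh units).

Integration is fixed-step RK4 on the observation grid
(discretize-then-optimize): gradients of any functional of the discrete
trajectory are computed exactly by the reverse sweep in
:func:`integrate_scaled_vjp`, with respect to the network weights, the
initial state and the (scaled) parameter vector.  This module is pure
NumPy and batches all records simultaneously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .parameters import ParameterSpace, ParameterVector
from .traces import CHANNELS, PVTrace

__all__ = [
    "SurrogateConfig",
    "SurrogateState",
    "TrainedSurrogate",
    "ChannelScalers",
    "clock_features",
    "rhs",
    "integrate",
    "init_weights",
    "save_surrogate",
    "load_surrogate",
]

N_PHYSICAL = 8


# ---------------------------------------------------------------------------
# configuration and state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateConfig:
    """Architecture of the neural right-hand side.

    ``n_latent`` is the number of latent states beyond the 8 physical ones
    (``N_z = 8 + n_latent``); ``l2_weight`` is the L2 regularization
    coefficient applied to the network weights during training.
    """

    n_latent: int = 0
    hidden_layers: int = 3
    neurons_per_layer: int = 13
    activation: str = "tanh"
    l2_weight: float = 1e-5

    def __post_init__(self):
        if self.n_latent < 0 or self.hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValueError("invalid architecture sizes")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be nonnegative")
        if self.activation != "tanh":
            raise ValueError("only the tanh activation is implemented")

    @property
    def n_states(self) -> int:
        return N_PHYSICAL + self.n_latent

    def layer_dims(self, n_params: int) -> list[int]:
        d_in = self.n_states + 2 + n_params
        return [d_in] + [self.neurons_per_layer] * self.hidden_layers + [self.n_states]


@dataclass(frozen=True)
class SurrogateState:
    """One point of the surrogate state: scaled physical + latent parts."""

    z_physical: np.ndarray
    z_latent: np.ndarray

    def __post_init__(self):
        zp = np.atleast_1d(np.asarray(self.z_physical, float))
        zl = np.atleast_1d(np.asarray(self.z_latent, float)) if np.size(self.z_latent) else np.empty(0)
        if zp.shape[-1] != N_PHYSICAL:
            raise ValueError(f"z_physical must have {N_PHYSICAL} entries")
        object.__setattr__(self, "z_physical", zp)
        object.__setattr__(self, "z_latent", zl)

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.z_physical, self.z_latent])


@dataclass(frozen=True)
class ChannelScalers:
    """Invertible per-channel affine maps between physical and scaled states.

    ``scaled = (physical - center) / half_range``; fitted so the training
    set maps into roughly ``[-1, 1]`` per channel.
    """

    center: np.ndarray
    half_range: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, float)
        h = np.asarray(self.half_range, float)
        if c.shape != (N_PHYSICAL,) or h.shape != (N_PHYSICAL,):
            raise ValueError("scalers must cover the 8 physical channels")
        if np.any(h <= 0):
            raise ValueError("half_range must be strictly positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "half_range", h)

    @classmethod
    def fit(cls, traces: np.ndarray) -> "ChannelScalers":
        """Fit from stacked traces of shape ``(..., 8)``."""
        flat = traces.reshape(-1, N_PHYSICAL)
        lo, hi = flat.min(axis=0), flat.max(axis=0)
        half = np.maximum((hi - lo) / 2.0, 1e-8)
        return cls((hi + lo) / 2.0, half)

    def scale(self, physical: np.ndarray) -> np.ndarray:
        return (physical - self.center) / self.half_range

    def unscale(self, scaled: np.ndarray) -> np.ndarray:
        return self.center + scaled * self.half_range


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def init_weights(config: SurrogateConfig, n_params: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Glorot-initialized layer weights ``[(W_0, b_0), ...]``."""
    rng = np.random.default_rng(int(seed))
    dims = config.layer_dims(n_params)
    out = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        s = np.sqrt(6.0 / (d_in + d_out))
        out.append((rng.uniform(-s, s, (d_in, d_out)), np.zeros(d_out)))
    return out


def pack_weights(weights: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in weights])


def unpack_weights(flat: np.ndarray, config: SurrogateConfig, n_params: int):
    dims = config.layer_dims(n_params)
    out, k = [], 0
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        W = flat[k:k + d_in * d_out].reshape(d_in, d_out)
        k += d_in * d_out
        b = flat[k:k + d_out]
        k += d_out
        out.append((W, b))
    if k != flat.size:
        raise ValueError(f"weight vector has {flat.size} entries, expected {k}")
    return out


def n_weights(config: SurrogateConfig, n_params: int) -> int:
    dims = config.layer_dims(n_params)
    return sum(di * do + do for di, do in zip(dims[:-1], dims[1:]))


# ---------------------------------------------------------------------------
# network forward / VJP (batched over rows)
# ---------------------------------------------------------------------------

def _mlp_forward(weights, U):
    """Feedforward tanh MLP.  Returns output and per-layer activation cache."""
    acts = [U]
    h = U
    for W, b in weights[:-1]:
        h = np.tanh(h @ W + b)
        acts.append(h)
    W, b = weights[-1]
    return h @ W + b, acts


def _mlp_vjp(weights, acts, cot, grads=None):
    """VJP of :func:`_mlp_forward` for cotangent ``cot`` on the output.

    Returns the cotangent on the input rows; if ``grads`` (a list shaped
    like ``weights``) is given, accumulates weight gradients into it.
    """
    d = cot
    for li in range(len(weights) - 1, -1, -1):
        W, _ = weights[li]
        a_in = acts[li]
        if grads is not None:
            gW, gb = grads[li]
            gW += a_in.T @ d
            gb += d.sum(axis=0)
        d = d @ W.T
        if li > 0:
            d = d * (1.0 - acts[li] ** 2)
    return d


# ---------------------------------------------------------------------------
# clock features and the public RHS
# ---------------------------------------------------------------------------

def clock_features(t, T_HB, AV_delay):
    """Periodic clock inputs ``(cos, sin)`` of phase ``2*pi*(t - AV_delay)/T_HB``."""
    T_HB = np.asarray(T_HB, float)
    if np.any(T_HB <= 0):
        raise ValueError("T_HB must be positive")
    phase = 2.0 * np.pi * (np.asarray(t, float) - np.asarray(AV_delay, float)) / T_HB
    return np.cos(phase), np.sin(phase)


@dataclass
class TrainedSurrogate:
    """A trained LNODE surrogate: weights, scalers and provenance.

    The ANN maps ``R^{N_z + 2 + N_P} -> R^{N_z}``; ``z0_latent`` holds the
    trained latent initial conditions; ``scalers`` map physical units to the
    scaled integration space, and the parameter scaling is the affine map of
    ``space`` onto ``[-1, 1]^{N_P}``.
    """

    config: SurrogateConfig
    weights: list[tuple[np.ndarray, np.ndarray]]
    z0_latent: np.ndarray
    scalers: ChannelScalers
    space: ParameterSpace
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        dims = self.config.layer_dims(len(self.space))
        got = [W.shape for W, _ in self.weights]
        want = [(a, b) for a, b in zip(dims[:-1], dims[1:])]
        if got != want:
            raise ValueError(f"weight shapes {got} do not match architecture {want}")
        self.z0_latent = np.asarray(self.z0_latent, float).reshape(self.config.n_latent)

    @property
    def n_weights(self) -> int:
        return pack_weights(self.weights).size

    def scale_theta(self, theta: ParameterVector) -> np.ndarray:
        if theta.space.names != self.space.names:
            raise ValueError("parameter vector does not belong to the surrogate's space")
        return theta.scaled()


def rhs(state: SurrogateState, t: float, theta: ParameterVector,
        model: TrainedSurrogate, T_HB: float, AV_delay: float) -> np.ndarray:
    """Evaluate dz/dt (scaled units) at one state and time.

    Time enters only through the periodic clock features; ``theta`` is fed
    to the network as constant input neurons after scaling to ``[-1, 1]``.
    """
    z = state.full
    if z.size != model.config.n_states:
        raise ValueError(
            f"state has {z.size} entries, model expects {model.config.n_states}"
        )
    c, s = clock_features(t, T_HB, AV_delay)
    u = np.concatenate([z, [c, s], model.scale_theta(theta)])[None, :]
    out, _ = _mlp_forward(model.weights, u)
    return out[0]


# ---------------------------------------------------------------------------
# batched fixed-step RK4 with exact reverse sweep
# ---------------------------------------------------------------------------

def integrate_scaled(weights, Z0, theta_s, T_HB, AV_delay, dt, n_steps,
                     keep_cache: bool = False, t_start=None):
    """RK4 over ``n_steps`` uniform steps, batched over rows.

    Parameters are per-row arrays: ``Z0 (R, N_z)``, ``theta_s (R, N_P)``,
    ``T_HB, AV_delay, dt`` each ``(R,)``; ``t_start`` optionally offsets each
    row's clock (segment-wise training).  Returns the trajectory
    ``Z (R, n_steps+1, N_z)``, the node RHS values ``K1 (R, n_steps, N_z)``
    (the exact network derivative along the solution) and, if requested,
    the cache needed by :func:`integrate_scaled_vjp`.
    """
    R, Nz = Z0.shape
    dt = np.asarray(dt, float).reshape(R, 1)
    T_HB = np.asarray(T_HB, float).reshape(R, 1)
    AV = np.asarray(AV_delay, float).reshape(R, 1)
    t_off = (np.zeros((R, 1)) if t_start is None
             else np.asarray(t_start, float).reshape(R, 1))
    omega = 2.0 * np.pi / T_HB

    Z = np.empty((R, n_steps + 1, Nz))
    K1 = np.empty((R, n_steps, Nz))
    Z[:, 0] = Z0
    caches = [] if keep_cache else None

    def f(z, t_col, cache_list):
        ph = omega * (t_col - AV)
        U = np.concatenate([z, np.cos(ph), np.sin(ph), theta_s], axis=1)
        out, acts = _mlp_forward(weights, U)
        if cache_list is not None:
            cache_list.append(acts)
        return out

    z = Z0
    for n in range(n_steps):
        t0 = t_off + n * dt
        step_cache = [] if keep_cache else None
        k1 = f(z, t0, step_cache)
        k2 = f(z + 0.5 * dt * k1, t0 + 0.5 * dt, step_cache)
        k3 = f(z + 0.5 * dt * k2, t0 + 0.5 * dt, step_cache)
        k4 = f(z + dt * k3, t0 + dt, step_cache)
        K1[:, n] = k1
        z = z + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(z)):
            raise FloatingPointError(f"non-finite surrogate state at step {n + 1}")
        Z[:, n + 1] = z
        if keep_cache:
            caches.append(step_cache)
    return Z, K1, caches


def integrate_scaled_vjp(weights, Z, caches, theta_s, dt, Z_bar, K1_bar=None):
    """Reverse sweep of :func:`integrate_scaled`.

    ``Z_bar (R, n_steps+1, N_z)`` are cotangents on the trajectory nodes and
    ``K1_bar (R, n_steps, N_z)`` optional cotangents on the node RHS values.
    Returns ``(grads, Z0_bar, theta_bar)`` where ``grads`` matches the layer
    structure of ``weights``.
    """
    R, n_nodes, Nz = Z.shape
    n_steps = n_nodes - 1
    dt = np.asarray(dt, float).reshape(R, 1)
    grads = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    theta_bar = np.zeros_like(theta_s)

    def back(acts, cot):
        u_bar = _mlp_vjp(weights, acts, cot, grads)
        theta_bar[...] += u_bar[:, Nz + 2:]
        return u_bar[:, :Nz]

    a = Z_bar[:, n_steps].copy()
    for n in range(n_steps - 1, -1, -1):
        c1, c2, c3, c4 = caches[n]
        h = dt
        k4_bar = (h / 6.0) * a
        v4 = back(c4, k4_bar)
        k3_bar = (h / 3.0) * a + h * v4
        v3 = back(c3, k3_bar)
        k2_bar = (h / 3.0) * a + 0.5 * h * v3
        v2 = back(c2, k2_bar)
        k1_bar = (h / 6.0) * a + 0.5 * h * v2
        if K1_bar is not None:
            k1_bar = k1_bar + K1_bar[:, n]
        v1 = back(c1, k1_bar)
        a = a + v1 + v2 + v3 + v4
        a += Z_bar[:, n]
    return grads, a, theta_bar


def integrate(model: TrainedSurrogate, theta: ParameterVector,
              z0_physical: np.ndarray, T_HB: float, AV_delay: float,
              grid: np.ndarray) -> tuple[PVTrace, np.ndarray]:
    """Integrate the surrogate on a uniform grid in ``[0, T_HB)``.

    ``z0_physical`` holds the 8 initial physical values (physical units);
    latent states start at the model's trained ``z0_latent``.  Returns the
    predicted :class:`~pvlnode.traces.PVTrace` in physical units plus the
    latent trajectory on the same grid.
    """
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("grid must be a 1-D array with >= 2 nodes")
    dt = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), dt):
        raise ValueError("grid must be uniform")
    z0p = model.scalers.scale(np.asarray(z0_physical, float))
    Z0 = np.concatenate([z0p, model.z0_latent])[None, :]
    theta_s = model.scale_theta(theta)[None, :]
    try:
        Z, _, _ = integrate_scaled(
            model.weights, Z0, theta_s, np.array([T_HB]), np.array([AV_delay]),
            np.array([dt]), len(grid) - 1,
        )
    except FloatingPointError as e:
        raise FloatingPointError(f"surrogate diverged: {e}") from e
    Z = Z[0, :len(grid)]
    physical = model.scalers.unscale(Z[:, :N_PHYSICAL])
    # volumes can graze zero on a badly-fit model; PVTrace enforces > 0
    trace = PVTrace(grid, np.maximum(physical, np.where(
        [c.startswith("V") for c in CHANNELS], 1e-6, -np.inf)), T_HB, AV_delay)
    return trace, Z[:, N_PHYSICAL:]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_surrogate(model: TrainedSurrogate, path: str | Path) -> None:
    """Write the surrogate to HDF5 with a human-readable JSON sidecar."""
    import h5py

    path = Path(path)
    cfg = model.config
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(
            {k: getattr(cfg, k) for k in
             ("n_latent", "hidden_layers", "neurons_per_layer", "activation", "l2_weight")}
        )
        f.attrs["space"] = json.dumps(model.space.to_dict())
        f.attrs["meta"] = json.dumps(model.meta, default=str)
        f.create_dataset("weights_flat", data=pack_weights(model.weights))
        f.create_dataset("z0_latent", data=model.z0_latent)
        f.create_dataset("scaler_center", data=model.scalers.center)
        f.create_dataset("scaler_half_range", data=model.scalers.half_range)
    sidecar = {
        "config": json.loads(h5_attr(path, "config")),
        "space": model.space.to_dict(),
        "n_weights": model.n_weights,
        "meta": model.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )


def h5_attr(path, name):
    import h5py

    with h5py.File(path, "r") as f:
        return f.attrs[name]


def load_surrogate(path: str | Path) -> TrainedSurrogate:
    import h5py

    with h5py.File(path, "r") as f:
        cfg = SurrogateConfig(**json.loads(f.attrs["config"]))
        space = ParameterSpace.from_dict(json.loads(f.attrs["space"]))
        meta = json.loads(f.attrs["meta"])
        flat = f["weights_flat"][...]
        z0_latent = f["z0_latent"][...]
        scalers = ChannelScalers(f["scaler_center"][...], f["scaler_half_range"][...])
    return TrainedSurrogate(
        cfg, unpack_weights(flat, cfg, len(space)), z0_latent, scalers, space, meta
    )
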