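"""Continuous-time gated recurrent rate network.

Each unit is a firing-rate neuron with an update gate ``phi`` and a
reset gate ``psi``.  With leak factor ``eta = dt/tau`` the discretised
dynamics of the hidden state ``h`` are

    phi(t) = sigmoid(W_rec_upd' x(t-1) + W_in_upd' u(t) + b_upd)
    psi(t) = sigmoid(W_rec_res' x(t-1) + W_in_res' u(t) + b_res)
    h(t)   = (1 - eta*phi(t)) h(t-1)
             + eta*phi(t) [ W_rec' (psi(t) * x(t-1)) + W_in' u(t) + b + xi(t) ]
    x(t)   = max(h(t), 0)

where ``x`` is the rate vector entering the recurrence (rectified, so
rates are non-negative), ``u(t)`` the input, and ``xi`` additive
Gaussian process noise with standard deviation sqrt(2*noise_var/eta)
inside the candidate drive.  Sparse connectivity is enforced with fixed
binary masks, one per projection (input / recurrent), shared by the
candidate and both gate matrices: a connection either exists or not.

Gradients are computed by backpropagation through time in
:func:`backward_sequence`; the forward pass caches everything needed.
All arrays are batch-last-free: matrices act on the right, states have
shape ``(batch, n_units)`` (or ``(n_units,)`` for single samples).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "GruConfig",
    "GruParams",
    "GruState",
    "init_params",
    "gru_step",
    "forward_sequence",
    "backward_sequence",
    "run_sequence",
    "noise_sd",
    "zero_grads",
    "save_params",
    "load_params",
]


@dataclass(frozen=True)
class GruConfig:
    n_units: int
    n_inputs: int
    dt: float = 20.0
    tau: float = 100.0
    noise_var: float = 0.01
    p_in: float = 1.0
    p_rec: float = 1.0

    def __post_init__(self):
        if not 0 < self.eta <= 1:
            raise ValueError(f"eta = dt/tau = {self.eta} must lie in (0, 1]")
        if self.noise_var < 0:
            raise ValueError("noise variance must be non-negative")
        for p in (self.p_in, self.p_rec):
            if not 0 <= p <= 1:
                raise ValueError("connection probabilities must lie in [0, 1]")

    @property
    def eta(self) -> float:
        return self.dt / self.tau


@dataclass
class GruParams:
    """Weights, biases and the fixed sparsity masks of one layer.

    Shapes: recurrent matrices ``(n_units, n_units)`` with entry [j, i]
    the weight from unit j to unit i; input matrices
    ``(n_inputs, n_units)``; biases ``(n_units,)``.
    """

    W_rec: np.ndarray
    W_rec_upd: np.ndarray
    W_rec_res: np.ndarray
    W_in: np.ndarray
    W_in_upd: np.ndarray
    W_in_res: np.ndarray
    b: np.ndarray
    b_upd: np.ndarray
    b_res: np.ndarray
    M_in: np.ndarray
    M_rec: np.ndarray

    WEIGHT_FIELDS = (
        "W_rec", "W_rec_upd", "W_rec_res",
        "W_in", "W_in_upd", "W_in_res",
        "b", "b_upd", "b_res",
    )

    def mask_of(self, name: str) -> np.ndarray | None:
        if name.startswith("W_rec"):
            return self.M_rec
        if name.startswith("W_in"):
            return self.M_in
        return None

    def apply_masks(self) -> None:
        for name in self.WEIGHT_FIELDS:
            mask = self.mask_of(name)
            if mask is not None:
                getattr(self, name)[:] *= mask

    def copy(self) -> "GruParams":
        return GruParams(**{f.name: getattr(self, f.name).copy() for f in fields(self)})


@dataclass
class GruState:
    h: np.ndarray
    x: np.ndarray
    phi: np.ndarray
    psi: np.ndarray


def noise_sd(config: GruConfig) -> float:
    """Std of the additive candidate-drive noise: sqrt(2*noise_var/eta)."""
    return float(np.sqrt(2.0 * config.noise_var / config.eta))


def init_params(config: GruConfig, rng: np.random.Generator) -> GruParams:
    """Draw masks and weights.

    Masks are Bernoulli(p) per connection, one shared mask per
    projection.  Weights are zero-mean Gaussian scaled by the expected
    fan-in of the sparse projection; biases start at zero.
    """
    n, m = config.n_units, config.n_inputs
    M_rec = (rng.random((n, n)) < config.p_rec).astype(float)
    M_in = (rng.random((m, n)) < config.p_in).astype(float)
    rec_sd = 1.0 / np.sqrt(max(1.0, config.p_rec * n))
    in_sd = 1.0 / np.sqrt(max(1.0, config.p_in * m))

    def draw(shape, sd):
        return rng.normal(0.0, sd, size=shape)

    params = GruParams(
        W_rec=draw((n, n), rec_sd) * M_rec,
        W_rec_upd=draw((n, n), rec_sd) * M_rec,
        W_rec_res=draw((n, n), rec_sd) * M_rec,
        W_in=draw((m, n), in_sd) * M_in,
        W_in_upd=draw((m, n), in_sd) * M_in,
        W_in_res=draw((m, n), in_sd) * M_in,
        b=np.zeros(n),
        b_upd=np.zeros(n),
        b_res=np.zeros(n),
        M_in=M_in,
        M_rec=M_rec,
    )
    return params


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def gru_step(
    config: GruConfig,
    params: GruParams,
    h_prev: np.ndarray,
    u_t: np.ndarray,
    eps: np.ndarray | None = None,
) -> GruState:
    """One step of the gated dynamics.

    ``eps`` is a standard-normal draw per unit (or ``None`` to disable
    process noise); it enters the candidate drive scaled by
    sqrt(2*noise_var/eta).
    """
    h_prev = np.asarray(h_prev, dtype=float)
    u_t = np.asarray(u_t, dtype=float)
    if h_prev.shape[-1] != config.n_units or u_t.shape[-1] != config.n_inputs:
        raise ValueError(
            f"shape mismatch: h {h_prev.shape}, u {u_t.shape} for "
            f"(n_units={config.n_units}, n_inputs={config.n_inputs})"
        )
    eta = config.eta
    x_prev = np.maximum(h_prev, 0.0)
    phi = _sigmoid(x_prev @ params.W_rec_upd + u_t @ params.W_in_upd + params.b_upd)
    psi = _sigmoid(x_prev @ params.W_rec_res + u_t @ params.W_in_res + params.b_res)
    cand = (psi * x_prev) @ params.W_rec + u_t @ params.W_in + params.b
    if eps is not None:
        cand = cand + noise_sd(config) * eps
    h = (1.0 - eta * phi) * h_prev + eta * phi * cand
    return GruState(h=h, x=np.maximum(h, 0.0), phi=phi, psi=psi)


def forward_sequence(
    config: GruConfig,
    params: GruParams,
    U: np.ndarray,
    noise: np.ndarray | None = None,
    h0: np.ndarray | None = None,
) -> dict:
    """Run the layer over a whole input sequence, caching for BPTT.

    ``U`` has shape (T, ..., n_inputs); ``noise`` (T, ..., n_units) holds
    pre-drawn standard-normal values or is ``None``.  The initial hidden
    state is zero unless ``h0`` is given.  Returns a cache dict with
    stacked per-step arrays (H, X, PHI, PSI, CAND, XPREV).
    """
    T = U.shape[0]
    batch_shape = U.shape[1:-1]
    n = config.n_units
    h = np.zeros(batch_shape + (n,)) if h0 is None else np.array(h0, dtype=float)
    H = np.empty((T,) + batch_shape + (n,))
    X = np.empty_like(H)
    PHI = np.empty_like(H)
    PSI = np.empty_like(H)
    CAND = np.empty_like(H)
    XPREV = np.empty_like(H)
    eta = config.eta
    # input drives do not depend on the state: project the whole sequence once
    drive_upd = U @ params.W_in_upd + params.b_upd
    drive_res = U @ params.W_in_res + params.b_res
    drive_cand = U @ params.W_in + params.b
    if noise is not None:
        drive_cand = drive_cand + noise_sd(config) * noise
    W_gates = np.concatenate([params.W_rec_upd, params.W_rec_res], axis=1)
    for t in range(T):
        x_prev = np.maximum(h, 0.0)
        gates = x_prev @ W_gates
        phi = _sigmoid(gates[..., :n] + drive_upd[t])
        psi = _sigmoid(gates[..., n:] + drive_res[t])
        cand = (psi * x_prev) @ params.W_rec + drive_cand[t]
        h = (1.0 - eta * phi) * h + eta * phi * cand
        XPREV[t], PHI[t], PSI[t], CAND[t], H[t] = x_prev, phi, psi, cand, h
        X[t] = np.maximum(h, 0.0)
    return {"U": U, "H": H, "X": X, "PHI": PHI, "PSI": PSI, "CAND": CAND, "XPREV": XPREV}


def run_sequence(
    config: GruConfig,
    params: GruParams,
    U: np.ndarray,
    rng: np.random.Generator | None = None,
    noise_on: bool = False,
    h0: np.ndarray | None = None,
) -> dict:
    """Forward pass with internally drawn process noise (if enabled)."""
    noise = None
    if noise_on:
        if rng is None:
            raise ValueError("noise_on requires an rng")
        noise = rng.standard_normal(U.shape[:-1] + (config.n_units,))
    return forward_sequence(config, params, U, noise=noise, h0=h0)


def zero_grads(params: GruParams) -> dict[str, np.ndarray]:
    return {name: np.zeros_like(getattr(params, name)) for name in GruParams.WEIGHT_FIELDS}


def backward_sequence(
    config: GruConfig,
    params: GruParams,
    cache: dict,
    dX: np.ndarray,
) -> dict[str, np.ndarray]:
    """Backpropagation through time.

    ``dX[t]`` is the loss gradient with respect to the rectified rates
    x(t).  Returns gradients for every weight and bias, with the
    sparsity masks already applied (masked connections get exactly zero
    gradient, so they stay zero under any update rule).
    """
    U = cache["U"]
    H, PHI, PSI, CAND, XPREV = (cache[k] for k in ("H", "PHI", "PSI", "CAND", "XPREV"))
    T = U.shape[0]
    n = config.n_units
    eta = config.eta
    g = zero_grads(params)

    # per-step pre-activation gradients, contracted against the cached
    # activities in single tensordots after the time loop
    DCAND = np.empty_like(H)
    DA_PHI = np.empty_like(H)
    DA_PSI = np.empty_like(H)
    W_gates_T = np.concatenate([params.W_rec_upd, params.W_rec_res], axis=1).T
    dh_carry = np.zeros_like(H[0])
    dx_carry = np.zeros_like(H[0])
    for t in range(T - 1, -1, -1):
        dx = dX[t] + dx_carry
        dh = dh_carry + dx * (H[t] > 0)
        h_prev = H[t - 1] if t > 0 else np.zeros_like(H[0])
        phi, psi, cand, x_prev = PHI[t], PSI[t], CAND[t], XPREV[t]
        dcand = dh * eta * phi
        ds = dcand @ params.W_rec.T
        da_phi = (dh * eta * (cand - h_prev)) * phi * (1.0 - phi)
        da_psi = (ds * x_prev) * psi * (1.0 - psi)
        DCAND[t], DA_PHI[t], DA_PSI[t] = dcand, da_phi, da_psi
        da_gates = np.concatenate([da_phi, da_psi], axis=-1)
        dx_carry = ds * psi + da_gates @ W_gates_T
        dh_carry = dh * (1.0 - eta * phi)

    def contract(A, B):  # sum_t,batch A[t]^T B[t]
        k = A.shape[-1]
        return A.reshape(-1, k).T @ B.reshape(-1, B.shape[-1])

    S = PSI * XPREV
    g["W_rec"] = contract(S, DCAND)
    g["W_rec_upd"] = contract(XPREV, DA_PHI)
    g["W_rec_res"] = contract(XPREV, DA_PSI)
    g["W_in"] = contract(U, DCAND)
    g["W_in_upd"] = contract(U, DA_PHI)
    g["W_in_res"] = contract(U, DA_PSI)
    g["b"] = DCAND.reshape(-1, n).sum(axis=0)
    g["b_upd"] = DA_PHI.reshape(-1, n).sum(axis=0)
    g["b_res"] = DA_PSI.reshape(-1, n).sum(axis=0)
    for name in GruParams.WEIGHT_FIELDS:
        mask = params.mask_of(name)
        if mask is not None:
            g[name] *= mask
    return g


def save_params(path, params: GruParams, prefix: str = "") -> None:
    """Serialize to a .npz container with one named dataset per array."""
    np.savez(path, **{prefix + f.name: getattr(params, f.name) for f in fields(GruParams)})


def load_params(path, prefix: str = "") -> GruParams:
    with np.load(path) as data:
        return GruParams(**{f.name: data[prefix + f.name] for f in fields(GruParams)})
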