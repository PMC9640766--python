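"""Actor-critic policy-gradient training on the paired-association task.

One *iteration* is a batch of 24 trials rolled out with the current
policy, followed by a single parameter update of both networks.  The
policy objective is the REINFORCE surrogate with the critic's
prediction subtracted from the episode return (the advantage); the
value objective is the per-trial mean-squared error between the
critic's per-step prediction and its target (the immediate reward by
default, the episode return as a config switch).  Gradients flow by
backpropagation through time over each episode; advantages and the
policy rates entering the critic are treated as constants.

Training alternates learn blocks (50 iterations with updates) and test
blocks (800 trials with frozen parameters); the run stops when the
correct-trial rate of a test block reaches 98% (both choices correct)
or at the iteration cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import gru
from .agent import Agent, AgentConfig, softmax
from .task import (
    TaskTiming,
    TrialSampler,
    TrialSpec,
    build_schedule,
    observation_matrix,
)

__all__ = [
    "TrainConfig",
    "Trajectory",
    "RolloutBatch",
    "TestResult",
    "TestRecording",
    "Checkpoint",
    "TrainingRun",
    "rollout",
    "rollout_batch",
    "advantage",
    "policy_objective",
    "value_objective",
    "update",
    "evaluate",
    "train",
    "analysis_windows",
]

_A_F, _A_L, _A_R = 0, 1, 2


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.01       # value network (alpha)
    policy_learning_rate: float = 0.3  # policy network (see docs/methods.md)
    n_trials: int = 24            # trials per parameter update
    learn_block: int = 50         # iterations between test blocks
    test_trials: int = 800
    convergence_threshold: float = 0.98
    max_iterations: int = 12000
    optimizer: str = "sgd"        # policy optimizer: "sgd" or "adam"
    value_optimizer: str = "sgd"
    clip_norm: float = 2.0
    value_target: str = "return"  # "return" (episode total) or "reward" (immediate)
    advantage_mode: str = "return"  # "return" (episode total) or "to-go"
    #: policy-gradient baseline: "value" subtracts the critic's per-step
    #: prediction; "batch" the mean return of the update batch;
    #: "value-centered" (default) subtracts the critic prediction and
    #: re-centres on the batch so that consistently failing conditions
    #: keep a corrective advantage even once the critic predicts them.
    advantage_baseline: str = "value-centered"
    #: critic's action input: the action layer's activity
    #: ("probabilities") or the sampled one-hot action ("sampled").
    value_action_input: str = "probabilities"
    #: L2 regularization on the policy readout (weights and biases).  A
    #: saturated softmax has zero policy gradient, so states that
    #: saturate before they are correct would freeze permanently; the
    #: decay supplies a desaturation pressure that acts exactly where
    #: the reward gradient vanishes.
    head_decay: float = 1e-3
    #: L2 regularization on the left/right *difference* of the readout.
    #: It pulls the side preference toward indifference, so a premature
    #: arbitrary side commitment (zero-gradient once saturated) decays
    #: and the stimulus-conditional side preference must be maintained
    #: by reward; it never touches the fixate-vs-choose axis.
    side_decay: float = 3e-3
    fixed_t_normalization: bool = False  # normalize M_n by full T+1 even when truncated


# --------------------------------------------------------------------------
# single-trial rollout (reference path; the batched path is used in training)


@dataclass
class Trajectory:
    spec: TrialSpec
    observations: np.ndarray   # (T_n, 11)
    rates: np.ndarray          # (T_n, N_p)
    actions: np.ndarray        # (T_n,) int
    log_probs: np.ndarray      # (T_n,)
    probs: np.ndarray          # (T_n, 3)
    values: np.ndarray         # (T_n,)
    rewards: np.ndarray        # (T_n,) reward credited at t+1
    events: list[str]
    first_correct: bool
    second_correct: bool

    @property
    def episode_return(self) -> float:
        return float(self.rewards.sum())

    @property
    def n_steps(self) -> int:
        return len(self.actions)


def rollout(agent: Agent, env, rng: np.random.Generator, spec: TrialSpec | None = None,
            noise_on: bool = True) -> Trajectory:
    """Run one trial with policy and value networks stepped in lockstep."""
    obs = env.reset(spec)
    agent.reset()
    rows = {k: [] for k in ("obs", "x", "a", "lp", "p", "v", "r")}
    events = []
    done = False
    while not done:
        action, lp, probs, x = agent.policy.step(obs, rng, noise_on=noise_on)
        onehot = np.zeros(agent.config.n_actions)
        onehot[("F", "L", "R").index(action)] = 1.0
        v = agent.value.step(x, onehot, rng, noise_on=noise_on)
        rows["obs"].append(obs)
        rows["x"].append(x)
        rows["a"].append(("F", "L", "R").index(action))
        rows["lp"].append(lp)
        rows["p"].append(probs)
        rows["v"].append(v)
        obs, reward, done, event = env.step(action)
        rows["r"].append(reward)
        events.append(event)
    return Trajectory(
        spec=env.spec,
        observations=np.asarray(rows["obs"]),
        rates=np.asarray(rows["x"]),
        actions=np.asarray(rows["a"], dtype=int),
        log_probs=np.asarray(rows["lp"]),
        probs=np.asarray(rows["p"]),
        values=np.asarray(rows["v"]),
        rewards=np.asarray(rows["r"]),
        events=events,
        first_correct=env.state.first_correct,
        second_correct=env.state.second_correct,
    )


def advantage(trajectory: Trajectory, mode: str = "return") -> np.ndarray:
    """Per-step advantage: episode return minus the critic's prediction.

    ``mode="to-go"`` replaces the full episode return with the return
    still to come from each step.
    """
    if mode == "return":
        base = np.full(trajectory.n_steps, trajectory.episode_return)
    elif mode == "to-go":
        base = np.cumsum(trajectory.rewards[::-1])[::-1]
    else:
        raise ValueError(f"unknown advantage mode {mode!r}")
    return base - trajectory.values


# --------------------------------------------------------------------------
# batched rollout


class _ObsCache:
    """Per-condition observation matrices, built once per schedule."""

    def __init__(self, schedule):
        self.schedule = schedule
        self._cache: dict[TrialSpec, np.ndarray] = {}

    def get(self, spec: TrialSpec) -> np.ndarray:
        mat = self._cache.get(spec)
        if mat is None:
            mat = observation_matrix(spec, self.schedule)
            self._cache[spec] = mat
        return mat


@dataclass
class RolloutBatch:
    specs: list[TrialSpec]
    U: np.ndarray              # (T, B, 11)
    policy_cache: dict
    value_cache: dict | None
    probs: np.ndarray          # (T, B, 3)
    actions: np.ndarray        # (T, B) int
    rewards: np.ndarray        # (T, B)
    mask: np.ndarray           # (T, B) 1.0 where the agent acted
    n_steps: np.ndarray        # (B,) realized action steps per trial
    values: np.ndarray | None  # (T, B)
    first_correct: np.ndarray  # (B,) bool
    second_correct: np.ndarray # (B,) bool
    choice2_step: np.ndarray   # (B,) step of the second choice, -1 if none

    @property
    def returns(self) -> np.ndarray:
        return self.rewards.sum(axis=0)

    @property
    def rates(self) -> np.ndarray:
        return self.policy_cache["X"]


def rollout_batch(
    agent: Agent,
    schedule,
    specs: list[TrialSpec],
    rng_noise: np.random.Generator,
    rng_action: np.random.Generator,
    noise_on: bool = True,
    obs_cache: _ObsCache | None = None,
    run_value: bool = True,
    value_action_input: str = "probabilities",
) -> RolloutBatch:
    """Roll out a batch of trials in lockstep.

    Observations depend only on the condition and the schedule (never on
    the agent's actions), so the policy network is advanced for all
    trials in parallel; termination only masks which steps contribute to
    rewards and losses.  The loop stops early once every trial is over.
    """
    B = len(specs)
    T_max = schedule.n_action_steps
    pcfg, pparams = agent.policy.config, agent.policy.params
    obs_cache = obs_cache or _ObsCache(schedule)
    U_full = np.stack([obs_cache.get(s) for s in specs], axis=1)  # (T, B, 11)

    d1a, d1b = schedule.range("first_decision")
    d2a, d2b = schedule.range("second_decision")
    pos1 = np.array([_A_L if s.pos1 == "left" else _A_R for s in specs])
    pos2 = np.array([_A_L if s.pos2 == "left" else _A_R for s in specs])

    n = pcfg.n_units
    eta = pcfg.eta
    sd = gru.noise_sd(pcfg)
    h = np.zeros((B, n))
    H = np.zeros((T_max, B, n))
    X = np.zeros_like(H)
    PHI = np.zeros_like(H)
    PSI = np.zeros_like(H)
    CAND = np.zeros_like(H)
    XPREV = np.zeros_like(H)
    probs_all = np.zeros((T_max, B, 3))
    actions = np.zeros((T_max, B), dtype=np.int64)
    rewards = np.zeros((T_max, B))
    mask = np.zeros((T_max, B))

    alive = np.ones(B, dtype=bool)
    chose1 = np.zeros(B, dtype=bool)
    chose2 = np.zeros(B, dtype=bool)
    first_correct = np.zeros(B, dtype=bool)
    second_correct = np.zeros(B, dtype=bool)
    choice2_step = np.full(B, -1, dtype=np.int64)

    drive_upd = U_full @ pparams.W_in_upd + pparams.b_upd
    drive_res = U_full @ pparams.W_in_res + pparams.b_res
    drive_cand = U_full @ pparams.W_in + pparams.b
    W_gates = np.concatenate([pparams.W_rec_upd, pparams.W_rec_res], axis=1)

    t_used = 0
    for t in range(T_max):
        x_prev = np.maximum(h, 0.0)
        gates = x_prev @ W_gates
        phi = _sigmoid(gates[:, :n] + drive_upd[t])
        psi = _sigmoid(gates[:, n:] + drive_res[t])
        cand = (psi * x_prev) @ pparams.W_rec + drive_cand[t]
        if noise_on:
            cand = cand + sd * rng_noise.standard_normal((B, n))
        h = (1.0 - eta * phi) * h + eta * phi * cand
        x = np.maximum(h, 0.0)
        XPREV[t], PHI[t], PSI[t], CAND[t], H[t], X[t] = x_prev, phi, psi, cand, h, x

        p = softmax(x @ agent.policy.W_out + agent.policy.b_out)
        probs_all[t] = p
        draws = rng_action.random(B)
        cum = np.cumsum(p, axis=1)
        a = (draws[:, None] >= cum).sum(axis=1)
        actions[t] = a
        mask[t, alive] = 1.0
        t_used = t + 1

        # --- environment transition, vectorised over the batch ----------
        act = alive  # trials that actually acted this step
        nonfix = act & (a != _A_F)
        if d1a <= t < d1b:
            choosing = nonfix & ~chose1
            correct = choosing & (a == pos1)
            wrong = choosing & (a != pos1)
            rewards[t, correct] = 1.0
            first_correct[correct] = True
            rewards[t, wrong] = -1.0
            alive[wrong] = False
            chose1[choosing] = True
            if t == d1b - 1:
                missed = act & ~chose1
                rewards[t, missed] = -1.0
                alive[missed] = False
        elif d2a <= t < d2b:
            choosing = nonfix & ~chose2
            correct = choosing & (a == pos2)
            wrong = choosing & (a != pos2)
            rewards[t, correct] = 1.0
            second_correct[correct] = True
            rewards[t, wrong] = 0.0
            chose2[choosing] = True
            choice2_step[choosing] = t
            if t == d2b - 1:
                missed = act & ~chose2
                rewards[t, missed] = -1.0
                alive[missed] = False
        else:
            broke = nonfix
            rewards[t, broke] = -1.0
            alive[broke] = False
        if not alive.any():
            break

    T = t_used
    sl = slice(0, T)
    policy_cache = {
        "U": U_full[sl], "H": H[sl], "X": X[sl], "PHI": PHI[sl], "PSI": PSI[sl],
        "CAND": CAND[sl], "XPREV": XPREV[sl],
    }
    probs_all = probs_all[sl]
    actions = actions[sl]
    rewards = rewards[sl]
    mask = mask[sl]

    values = None
    value_cache = None
    if run_value:
        if value_action_input == "probabilities":
            # the critic reads the action layer's activity; it cannot
            # condition on the sampled action, keeping the baseline
            # action-independent (see docs/methods.md)
            action_input = probs_all
        elif value_action_input == "sampled":
            action_input = np.zeros((T, B, agent.config.n_actions))
            tt, bb = np.meshgrid(np.arange(T), np.arange(B), indexing="ij")
            action_input[tt, bb, actions] = 1.0
        else:
            raise ValueError(f"unknown value_action_input {value_action_input!r}")
        Uv = np.concatenate([policy_cache["X"], action_input], axis=-1)
        vcfg = agent.value.config
        noise_v = rng_noise.standard_normal((T, B, vcfg.n_units)) if noise_on else None
        value_cache = gru.forward_sequence(vcfg, agent.value.params, Uv, noise=noise_v)
        values = value_cache["X"] @ agent.value.W_out + agent.value.b_out

    return RolloutBatch(
        specs=specs, U=U_full[sl], policy_cache=policy_cache, value_cache=value_cache,
        probs=probs_all, actions=actions, rewards=rewards, mask=mask,
        n_steps=mask.sum(axis=0).astype(int), values=values,
        first_correct=first_correct, second_correct=second_correct,
        choice2_step=choice2_step,
    )


def _sigmoid(a):
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


# --------------------------------------------------------------------------
# objectives and their gradients


def _batch_advantage(batch: RolloutBatch, mode: str) -> np.ndarray:
    if batch.values is None:
        raise ValueError("batch was rolled out without the value network")
    if mode == "return":
        base = batch.returns[None, :]
    elif mode == "to-go":
        csum = np.cumsum(batch.rewards[::-1], axis=0)[::-1]
        base = csum
    else:
        raise ValueError(f"unknown advantage mode {mode!r}")
    return (base - batch.values) * batch.mask


def policy_objective(
    agent: Agent, batch: RolloutBatch, config: TrainConfig
) -> tuple[float, dict[str, np.ndarray]]:
    """Surrogate policy loss (mean of -R_n) and its gradients.

    The gradient is sum_t grad log pi(a_t|u_t) * advantage_t per trial,
    averaged over the batch, backpropagated through time; advantages are
    constants with respect to the policy parameters.  The baseline is
    either the critic's prediction or the batch-mean return (default;
    see docs/methods.md for why).
    """
    B = len(batch.specs)
    if B == 0:
        raise ValueError("empty batch")
    if config.advantage_baseline == "batch":
        R = batch.returns
        adv = (R - R.mean())[None, :] * batch.mask
    elif config.advantage_baseline == "value":
        adv = _batch_advantage(batch, config.advantage_mode)
    elif config.advantage_baseline == "value-centered":
        # critic baseline re-centred on the batch: conditions that fail
        # while the rest of the batch succeeds keep a negative advantage
        # even once the critic predicts their failure
        adv = _batch_advantage(batch, config.advantage_mode)
        adv = (adv - (adv * batch.mask).sum() / batch.mask.sum()) * batch.mask
    else:
        raise ValueError(f"unknown advantage baseline {config.advantage_baseline!r}")
    T = batch.probs.shape[0]
    onehot = np.zeros_like(batch.probs)
    tt, bb = np.meshgrid(np.arange(T), np.arange(B), indexing="ij")
    onehot[tt, bb, batch.actions] = 1.0
    # d(-adv*log pi)/dz with z the logits
    dz = (batch.probs - onehot) * adv[:, :, None] * batch.mask[:, :, None] / B
    X = batch.policy_cache["X"]
    gW = np.einsum("tbn,tbk->nk", X, dz) + config.head_decay * agent.policy.W_out
    gb = dz.sum(axis=(0, 1)) + config.head_decay * agent.policy.b_out
    if config.side_decay:
        dW_side = agent.policy.W_out[:, 1] - agent.policy.W_out[:, 2]
        db_side = agent.policy.b_out[1] - agent.policy.b_out[2]
        gW[:, 1] += config.side_decay * dW_side
        gW[:, 2] -= config.side_decay * dW_side
        gb[1] += config.side_decay * db_side
        gb[2] -= config.side_decay * db_side
    grads = {"W_out": gW, "b_out": gb}
    dX = dz @ agent.policy.W_out.T
    grads.update(gru.backward_sequence(agent.policy.config, agent.policy.params,
                                       batch.policy_cache, dX))
    loss = float(-(batch.returns).mean())
    return loss, grads


def value_objective(
    agent: Agent, batch: RolloutBatch, config: TrainConfig
) -> tuple[float, dict[str, np.ndarray]]:
    """Per-trial mean-squared prediction error and its gradients.

    The default target is the immediate reward r_{t+1}; the "return"
    switch trains toward the episode total instead.  Normalisation uses
    the realized trial length T_n + 1 (rates past termination do not
    exist) unless ``fixed_t_normalization`` restores the full-length
    denominator.
    """
    B = len(batch.specs)
    if B == 0:
        raise ValueError("empty batch")
    if config.value_target == "reward":
        target = batch.rewards
    elif config.value_target == "return":
        target = np.broadcast_to(batch.returns[None, :], batch.rewards.shape)
    else:
        raise ValueError(f"unknown value target {config.value_target!r}")
    if config.fixed_t_normalization:
        denom = np.full(B, float(batch.U.shape[0] + 1))
    else:
        denom = batch.n_steps + 1.0
    err = (batch.values - target) * batch.mask
    per_trial = (err ** 2).sum(axis=0) / denom
    loss = float(per_trial.mean())
    dv = 2.0 * err / denom[None, :] / B
    Xv = batch.value_cache["X"]
    grads = {
        "W_out": np.einsum("tbn,tb->n", Xv, dv),
        "b_out": np.asarray(dv.sum()),
    }
    dXv = dv[:, :, None] * agent.value.W_out[None, None, :]
    grads.update(gru.backward_sequence(agent.value.config, agent.value.params,
                                       batch.value_cache, dXv))
    return loss, grads


# --------------------------------------------------------------------------
# optimiser


class Optimizer:
    """Adam (default) or plain SGD over named parameter groups."""

    def __init__(self, learning_rate: float, kind: str = "adam",
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if kind not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {kind!r}")
        self.lr = learning_rate
        self.kind = kind
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        if self.kind == "sgd":
            for k, gk in grads.items():
                params[k] -= self.lr * gk
            return
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, gk in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(gk)
                self.v[k] = np.zeros_like(gk)
            self.m[k] = b1 * self.m[k] + (1 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1 - b2) * gk * gk
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so their global norm is at most ``max_norm``."""
    total = math.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def _param_views(net) -> dict[str, np.ndarray]:
    views = {name: getattr(net.params, name) for name in gru.GruParams.WEIGHT_FIELDS}
    views["W_out"] = net.W_out
    return views


def update(agent: Agent, policy_grads: dict, value_grads: dict,
           opt_policy: Optimizer, opt_value: Optimizer, config: TrainConfig) -> dict:
    """One optimiser step on both networks; masked entries stay zero."""
    for grads in (policy_grads, value_grads):
        for g in grads.values():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient encountered")
    pn = clip_gradients(policy_grads, config.clip_norm)
    vn = clip_gradients(value_grads, config.clip_norm)

    pviews = _param_views(agent.policy)
    pviews["b_out"] = agent.policy.b_out
    opt_policy.step(pviews, {k: policy_grads[k] for k in pviews})

    vviews = _param_views(agent.value)
    b = np.asarray([agent.value.b_out])
    vviews["b_out"] = b
    vgrads = {k: value_grads[k] for k in vviews}
    vgrads["b_out"] = np.asarray([float(value_grads["b_out"])])
    opt_value.step(vviews, vgrads)
    agent.value.b_out = float(b[0])

    agent.policy.params.apply_masks()
    agent.value.params.apply_masks()
    return {"policy_grad_norm": pn, "value_grad_norm": vn}


# --------------------------------------------------------------------------
# evaluation (test blocks) and activity recording


def analysis_windows(schedule) -> dict[str, tuple[int, int]]:
    """Step ranges of the analysis windows (five task periods + baseline)."""
    s1a, s1b = schedule.range("first_stimulus")
    return {
        "baseline": (max(0, s1a - int(200 // schedule.timing.dt)), s1a),
        "first_stimulus": schedule.range("first_stimulus"),
        "first_delay": schedule.range("first_delay"),
        "second_stimulus": schedule.range("second_stimulus"),
        "second_delay": schedule.range("mid_fixation"),
        "third_stimulus": schedule.range("third_stimulus"),
        "first_decision": schedule.range("first_decision"),
        "stimulus_and_delay": (s1a, schedule.range("first_delay")[1]),
    }


@dataclass
class TestRecording:
    """Activity of the policy IIL on correct test trials.

    ``mean_traces[c]`` is the across-trial mean rate trace (T, N) for
    first-stimulus condition c (order A1, B1, C1, A2, B2, C2);
    ``window_rates`` holds per-trial window-averaged rates.
    """

    n_neurons: int
    windows: dict[str, tuple[int, int]]
    mean_traces: np.ndarray          # (6, T, N)
    trial_counts: np.ndarray         # (6,)
    window_rates: dict[str, np.ndarray]  # name -> (n_trials, N)
    condition: np.ndarray            # (n_trials,) first-stimulus index 0..5
    chosen_side: np.ndarray          # (n_trials,) 0=L, 1=R (first choice)
    rate_max: np.ndarray             # (N,) max rate seen on any analyzed trial


class _RecordingAccumulator:
    def __init__(self, n_neurons: int, T: int, windows: dict[str, tuple[int, int]],
                 tracked=("first_stimulus", "stimulus_and_delay", "first_decision"),
                 require: str = "both"):
        self.windows = windows
        self.tracked = tracked
        self.require = require
        self.trace_sum = np.zeros((6, T, n_neurons))
        self.counts = np.zeros(6, dtype=int)
        self.window_rates = {w: [] for w in tracked}
        self.condition = []
        self.side = []
        self.rate_max = np.zeros(n_neurons)

    def add(self, batch: RolloutBatch):
        if self.require == "both":
            ok = batch.first_correct & batch.second_correct
        elif self.require == "first":
            ok = batch.first_correct
        elif self.require == "reached-decision":
            # trials that held fixation through sample, delay and pair:
            # their first-stimulus-period rates are fully valid, whatever
            # the subsequent choices were
            d1a = self.windows["first_decision"][0]
            T = batch.mask.shape[0]
            ok = batch.mask[d1a] > 0 if T > d1a else np.zeros(batch.mask.shape[1], bool)
        elif self.require == "sample-complete":
            # trials that held fixation through the sample presentation;
            # the first-stimulus window is valid, later periods need not be
            s1b = self.windows["first_stimulus"][1]
            T = batch.mask.shape[0]
            ok = batch.mask[s1b - 1] > 0 if T >= s1b else np.zeros(batch.mask.shape[1], bool)
        else:
            raise ValueError(f"unknown trial filter {self.require!r}")
        if not ok.any():
            return
        X = batch.rates[:, ok, :]
        conds = np.array([s.first_stimulus_index for s in batch.specs])[ok]
        sides = np.array([0 if s.pos1 == "left" else 1 for s in batch.specs])[ok]
        for c in range(6):
            sel = conds == c
            if sel.any():
                self.trace_sum[c, : X.shape[0]] += X[:, sel, :].sum(axis=1)
                self.counts[c] += int(sel.sum())
        for w in self.tracked:
            a, b = self.windows[w]
            self.window_rates[w].append(X[a:b].mean(axis=0))
        self.condition.append(conds)
        self.side.append(sides)
        self.rate_max = np.maximum(self.rate_max, X.max(axis=(0, 1)))

    def finish(self) -> TestRecording | None:
        if self.counts.sum() == 0:
            return None
        traces = self.trace_sum / np.maximum(self.counts, 1)[:, None, None]
        return TestRecording(
            n_neurons=self.trace_sum.shape[2],
            windows=self.windows,
            mean_traces=traces,
            trial_counts=self.counts,
            window_rates={w: np.concatenate(v) for w, v in self.window_rates.items()},
            condition=np.concatenate(self.condition),
            chosen_side=np.concatenate(self.side),
            rate_max=self.rate_max,
        )


@dataclass
class TestResult:
    n_trials: int
    first_choice_rate: float
    correct_rate: float
    mean_reward: float
    value_mse_choice2: float
    recording: TestRecording | None = None


def evaluate(
    agent: Agent,
    schedule,
    n_trials: int,
    rng_task: np.random.Generator,
    rng_noise: np.random.Generator,
    rng_action: np.random.Generator,
    noise_on: bool = True,
    record: bool = True,
    chunk: int = 192,
    obs_cache: _ObsCache | None = None,
    value_action_input: str = "probabilities",
    record_require: str = "both",
) -> TestResult:
    """Run a frozen-parameter test block.

    Testing uses the same stochastic action sampling and process noise
    as training; only the updates are withheld.  ``record_require``
    selects which trials enter the activity recording: fully correct
    trials ("both", the default analysis condition) or trials with a
    correct first choice ("first").
    """
    sampler = TrialSampler(rng_task)
    obs_cache = obs_cache or _ObsCache(schedule)
    windows = analysis_windows(schedule)
    acc = _RecordingAccumulator(agent.config.n_policy_units, schedule.n_action_steps,
                                windows, require=record_require) \
        if record else None
    n_first = n_both = 0
    total_reward = 0.0
    mse_num, mse_den = 0.0, 0
    done = 0
    while done < n_trials:
        B = min(chunk, n_trials - done)
        specs = sampler.sample_block(B)
        batch = rollout_batch(agent, schedule, specs, rng_noise, rng_action,
                              noise_on=noise_on, obs_cache=obs_cache,
                              value_action_input=value_action_input)
        n_first += int(batch.first_correct.sum())
        n_both += int((batch.first_correct & batch.second_correct).sum())
        total_reward += float(batch.returns.sum())
        c2 = batch.choice2_step
        has2 = c2 >= 0
        if has2.any():
            idx = np.nonzero(has2)[0]
            v2 = batch.values[c2[idx], idx]
            r2 = batch.rewards[c2[idx], idx]
            mse_num += float(((r2 - v2) ** 2).sum())
            mse_den += len(idx)
        if acc is not None:
            acc.add(batch)
        done += B
    return TestResult(
        n_trials=n_trials,
        first_choice_rate=n_first / n_trials,
        correct_rate=n_both / n_trials,
        mean_reward=total_reward / n_trials,
        value_mse_choice2=mse_num / mse_den if mse_den else float("nan"),
        recording=acc.finish() if acc is not None else None,
    )


# --------------------------------------------------------------------------
# full training loop


def recording_with_fallback(
    agent: Agent,
    schedule,
    seed: int,
    n_trials: int = 800,
    first: TestRecording | None = None,
) -> tuple[TestRecording | None, str]:
    """Best usable activity recording for the selectivity analysis.

    Tries, in order: the given recording (fully correct trials), trials
    that reached the first decision window, trials that completed the
    sample presentation.  Returns the first recording with at least two
    trials in every first-stimulus condition, plus a tag naming the
    condition used.
    """
    def usable(rec):
        return rec is not None and rec.trial_counts.min() >= 2

    if usable(first):
        return first, "both-correct"
    streams = np.random.SeedSequence(seed).spawn(12)[-3:]
    for require in ("reached-decision", "sample-complete"):
        rngs = [np.random.default_rng(s) for s in streams]
        result = evaluate(agent, schedule, n_trials, *rngs,
                          record=True, record_require=require)
        if usable(result.recording):
            return result.recording, require
    return None, "none"


@dataclass
class Checkpoint:
    iteration: int
    first_choice_rate: float
    correct_rate: float
    mean_reward: float
    value_mse_choice2: float
    policy_params: gru.GruParams
    period_means: dict[str, np.ndarray] | None  # window -> (6, N) condition means
    recording: TestRecording | None = None


@dataclass
class TrainingRun:
    agent: Agent
    config: TrainConfig
    schedule: object
    converged: bool
    iterations: int
    checkpoints: list[Checkpoint]
    initial_policy_params: gru.GruParams
    log: list[dict] = field(default_factory=list)

    @property
    def final_checkpoint(self) -> Checkpoint:
        return self.checkpoints[-1]

    def log_frame(self):
        import pandas as pd

        return pd.DataFrame(self.log)


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named child streams of one master seed."""
    names = ("params", "task", "noise", "action", "bootstrap", "test_task",
             "test_noise", "test_action")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _period_means(recording: TestRecording | None, windows) -> dict[str, np.ndarray] | None:
    if recording is None:
        return None
    out = {}
    for name in ("first_stimulus", "first_delay", "second_stimulus",
                 "second_delay", "third_stimulus", "baseline"):
        a, b = windows[name]
        out[name] = recording.mean_traces[:, a:b, :].mean(axis=1)  # (6, N)
    return out


def train(
    seed: int,
    agent_config: AgentConfig | None = None,
    train_config: TrainConfig | None = None,
    timing: TaskTiming | None = None,
    progress: bool = False,
) -> TrainingRun:
    """Alternate learn blocks and frozen-parameter test blocks.

    Stops at the first test block whose correct-trial rate reaches the
    convergence threshold, or at the iteration cap (non-converged
    status).  Every source of randomness is a named child stream of the
    master seed.
    """
    agent_config = agent_config or AgentConfig()
    train_config = train_config or TrainConfig()
    timing = timing or TaskTiming()
    schedule = build_schedule(timing)
    rngs = _rng_streams(seed)
    agent = Agent.init(agent_config, rngs["params"])
    initial_policy = agent.policy.params.copy()
    opt_p = Optimizer(train_config.policy_learning_rate, train_config.optimizer)
    opt_v = Optimizer(train_config.learning_rate, train_config.value_optimizer)
    sampler = TrialSampler(rngs["task"])
    obs_cache = _ObsCache(schedule)
    windows = analysis_windows(schedule)

    checkpoints: list[Checkpoint] = []
    log: list[dict] = []
    converged = False
    iteration = 0
    while iteration < train_config.max_iterations and not converged:
        for _ in range(train_config.learn_block):
            if iteration >= train_config.max_iterations:
                break
            specs = sampler.sample_block(train_config.n_trials)
            batch = rollout_batch(agent, schedule, specs, rngs["noise"], rngs["action"],
                                  noise_on=True, obs_cache=obs_cache,
                                  value_action_input=train_config.value_action_input)
            ploss, pgrads = policy_objective(agent, batch, train_config)
            vloss, vgrads = value_objective(agent, batch, train_config)
            norms = update(agent, pgrads, vgrads, opt_p, opt_v, train_config)
            iteration += 1
            log.append({
                "iteration": iteration, "phase": "learn",
                "policy_loss": ploss, "value_loss": vloss,
                "mean_reward": float(batch.returns.mean()),
                "first_choice_rate": float(batch.first_correct.mean()),
                "correct_rate": float((batch.first_correct & batch.second_correct).mean()),
                **norms,
            })
        result = evaluate(agent, schedule, train_config.test_trials,
                          rngs["test_task"], rngs["test_noise"], rngs["test_action"],
                          noise_on=True, record=True, obs_cache=obs_cache,
                          value_action_input=train_config.value_action_input)
        converged = result.correct_rate >= train_config.convergence_threshold
        checkpoints.append(Checkpoint(
            iteration=iteration,
            first_choice_rate=result.first_choice_rate,
            correct_rate=result.correct_rate,
            mean_reward=result.mean_reward,
            value_mse_choice2=result.value_mse_choice2,
            policy_params=agent.policy.params.copy(),
            period_means=_period_means(result.recording, windows),
            recording=result.recording,
        ))
        log.append({
            "iteration": iteration, "phase": "test",
            "first_choice_rate": result.first_choice_rate,
            "correct_rate": result.correct_rate,
            "mean_reward": result.mean_reward,
            "value_mse_choice2": result.value_mse_choice2,
        })
        if progress:
            print(f"iter {iteration:5d}  first {result.first_choice_rate:6.3f}  "
                  f"both {result.correct_rate:6.3f}  reward {result.mean_reward:6.3f}",
                  flush=True)
        # keep only summaries for non-final checkpoints to bound memory
        if len(checkpoints) > 1 and not converged:
            checkpoints[-2].recording = None

    return TrainingRun(
        agent=agent, config=train_config, schedule=schedule,
        converged=converged, iterations=iteration,
        checkpoints=checkpoints, initial_policy_params=initial_policy, log=log,
    )
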