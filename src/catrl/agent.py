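"""Actor and critic networks.

The policy network maps the 11-channel task observation through a
sparsely connected 150-unit gated recurrent layer (the information
integration layer, IIL) to a 3-way softmax over the actions fixation /
left / right.  The value network is a dense 100-unit gated recurrent
layer that receives the policy IIL rates concatenated with a one-hot
copy of the sampled action (153 inputs) and reads out a scalar reward
prediction.  Both hidden states are reset between trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gru
from .task import ACTIONS

__all__ = ["AgentConfig", "PolicyNetwork", "ValueNetwork", "Agent", "softmax"]


@dataclass(frozen=True)
class AgentConfig:
    n_policy_units: int = 150
    n_value_units: int = 100
    n_policy_inputs: int = 11
    n_actions: int = 3
    p_in: float = 0.2     # input layer -> policy IIL
    p_rec: float = 0.1    # within policy IIL
    p_out: float = 1.0    # policy IIL -> action layer (full)
    dt: float = 20.0
    tau: float = 100.0
    noise_var: float = 0.01
    #: initial logit offset of the fixation action.  An untrained monkey
    #: enters this task already fixation-trained; without the offset the
    #: random policy terminates every trial within a few steps and the
    #: decision periods are never reached.
    fixation_bias: float = 4.6
    #: initial update-gate bias; negative values slow the leak
    #: (1 - eta*phi), lengthening intrinsic memory across the delays.
    update_gate_bias_init: float = -2.0

    @property
    def n_value_inputs(self) -> int:
        return self.n_policy_units + self.n_actions

    def policy_gru(self) -> gru.GruConfig:
        return gru.GruConfig(
            n_units=self.n_policy_units, n_inputs=self.n_policy_inputs,
            dt=self.dt, tau=self.tau, noise_var=self.noise_var,
            p_in=self.p_in, p_rec=self.p_rec,
        )

    def value_gru(self) -> gru.GruConfig:
        return gru.GruConfig(
            n_units=self.n_value_units, n_inputs=self.n_value_inputs,
            dt=self.dt, tau=self.tau, noise_var=self.noise_var,
            p_in=1.0, p_rec=1.0,
        )


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class PolicyNetwork:
    config: gru.GruConfig
    params: gru.GruParams
    W_out: np.ndarray  # (n_units, n_actions)
    b_out: np.ndarray  # (n_actions,)
    h: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def init(cls, agent_config: AgentConfig, rng: np.random.Generator) -> "PolicyNetwork":
        """Recurrent weights Gaussian/fan-in; readout starts at zero.

        A zero readout makes the initial policy state-independent: the
        only initial action preference is the fixation bias, and action
        logits become state-dependent only as learning shapes ``W_out``.
        """
        cfg = agent_config.policy_gru()
        params = gru.init_params(cfg, rng)
        params.b_upd[:] = agent_config.update_gate_bias_init
        b_out = np.zeros(agent_config.n_actions)
        b_out[0] = agent_config.fixation_bias
        return cls(
            config=cfg, params=params,
            W_out=np.zeros((cfg.n_units, agent_config.n_actions)),
            b_out=b_out,
        )

    def reset(self) -> None:
        self.h = np.zeros(self.config.n_units)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W_out + self.b_out

    def step(
        self,
        observation: np.ndarray,
        rng: np.random.Generator,
        noise_on: bool = True,
        greedy: bool = False,
    ) -> tuple[str, float, np.ndarray, np.ndarray]:
        """Advance one step and sample an action.

        Returns (action, log-probability of the sampled action, action
        probabilities, IIL rates).  Sampling from the softmax is the
        default; ``greedy`` takes the argmax for evaluation purposes.
        """
        observation = np.asarray(observation, dtype=float)
        if observation.shape != (self.config.n_inputs,):
            raise ValueError(f"observation must be a {self.config.n_inputs}-vector")
        if self.h is None:
            self.reset()
        eps = rng.standard_normal(self.config.n_units) if noise_on else None
        state = gru.gru_step(self.config, self.params, self.h, observation, eps)
        self.h = state.h
        probs = softmax(self.logits(state.x))
        if greedy:
            a = int(np.argmax(probs))
        else:
            a = int(rng.choice(len(ACTIONS), p=probs))
        return ACTIONS[a], float(np.log(probs[a])), probs, state.x


@dataclass
class ValueNetwork:
    config: gru.GruConfig
    params: gru.GruParams
    W_out: np.ndarray  # (n_units,)
    b_out: float
    h: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def init(cls, agent_config: AgentConfig, rng: np.random.Generator) -> "ValueNetwork":
        cfg = agent_config.value_gru()
        params = gru.init_params(cfg, rng)
        params.b_upd[:] = agent_config.update_gate_bias_init
        return cls(
            config=cfg, params=params,
            W_out=np.zeros(cfg.n_units),
            b_out=0.0,
        )

    def reset(self) -> None:
        self.h = np.zeros(self.config.n_units)

    def readout(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W_out + self.b_out

    def step(
        self,
        policy_rates: np.ndarray,
        action_onehot: np.ndarray,
        rng: np.random.Generator,
        noise_on: bool = True,
    ) -> float:
        """One critic step on (policy IIL rates, action indicator)."""
        u = np.concatenate([np.asarray(policy_rates, float), np.asarray(action_onehot, float)])
        if u.shape != (self.config.n_inputs,):
            raise ValueError(f"value input must have length {self.config.n_inputs}")
        if self.h is None:
            self.reset()
        eps = rng.standard_normal(self.config.n_units) if noise_on else None
        state = gru.gru_step(self.config, self.params, self.h, u, eps)
        self.h = state.h
        return float(self.readout(state.x))


@dataclass
class Agent:
    """Policy + value pair sharing one configuration."""

    config: AgentConfig
    policy: PolicyNetwork
    value: ValueNetwork

    @classmethod
    def init(cls, config: AgentConfig, rng: np.random.Generator) -> "Agent":
        return cls(config=config, policy=PolicyNetwork.init(config, rng),
                   value=ValueNetwork.init(config, rng))

    def reset(self) -> None:
        self.policy.reset()
        self.value.reset()

    # -- checkpointing -------------------------------------------------
    def save(self, path, iteration: int | None = None, rng_state: dict | None = None) -> None:
        """One array container holding both networks plus the heads."""
        from dataclasses import fields as dfields

        arrays: dict[str, np.ndarray] = {}
        for tag, net in (("policy", self.policy), ("value", self.value)):
            for f in dfields(gru.GruParams):
                arrays[f"{tag}.{f.name}"] = getattr(net.params, f.name)
            arrays[f"{tag}.W_out"] = np.asarray(net.W_out)
            arrays[f"{tag}.b_out"] = np.asarray(net.b_out)
        if iteration is not None:
            arrays["iteration"] = np.asarray(iteration)
        if rng_state is not None:
            import json

            arrays["rng_state_json"] = np.frombuffer(
                json.dumps(rng_state, default=str).encode(), dtype=np.uint8
            )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, config: AgentConfig | None = None) -> "Agent":
        from dataclasses import fields as dfields

        config = config or AgentConfig()
        with np.load(path) as data:
            nets = {}
            for tag, cfg in (("policy", config.policy_gru()), ("value", config.value_gru())):
                params = gru.GruParams(
                    **{f.name: data[f"{tag}.{f.name}"] for f in dfields(gru.GruParams)}
                )
                nets[tag] = (cfg, params, data[f"{tag}.W_out"], data[f"{tag}.b_out"])
        pc, pp, pw, pb = nets["policy"]
        vc, vp, vw, vb = nets["value"]
        return cls(
            config=config,
            policy=PolicyNetwork(config=pc, params=pp, W_out=pw, b_out=pb),
            value=ValueNetwork(config=vc, params=vp, W_out=vw, b_out=float(vb)),
        )
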