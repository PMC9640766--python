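"""Plain-text (YAML) configuration for task, agent and training.

The default values are the model's training parameters: learning rate
alpha = 0.01, dt = 20 ms, tau = 100 ms, 150/100 IIL units, connection
probabilities p_0 = 0.2, p_1 = 0.1, p_2 = 1, network noise 0.01 and 24
trials per update.  Keys accept both the package's field names and the
conventional short names (``alpha``, ``N_trials``, ``delta_rec2`` ...).
"""

from __future__ import annotations

import dataclasses

import yaml

from .agent import AgentConfig
from .task import TaskTiming
from .training import TrainConfig

__all__ = ["load_config", "save_config", "default_config_dict"]

_ALIASES = {
    "agent": {
        "N_p": "n_policy_units",
        "N_v": "n_value_units",
        "N_p_in": "n_policy_inputs",
        "N_p_out": "n_actions",
        "p_0": "p_in",
        "p_1": "p_rec",
        "p_2": "p_out",
        "delta_rec2": "noise_var",
    },
    "training": {
        "alpha": "learning_rate",
        "N_trials": "n_trials",
    },
    "task": {},
}


def default_config_dict() -> dict:
    return {
        "task": dataclasses.asdict(TaskTiming()),
        "agent": dataclasses.asdict(AgentConfig()),
        "training": dataclasses.asdict(TrainConfig()),
    }


def _build(section: str, cls, raw: dict):
    kwargs = {}
    aliases = _ALIASES[section]
    names = {f.name for f in dataclasses.fields(cls)}
    for key, value in (raw or {}).items():
        name = aliases.get(key, key)
        if name not in names:
            raise ValueError(f"unknown {section} option {key!r}")
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> tuple[TaskTiming, AgentConfig, TrainConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return (
        _build("task", TaskTiming, raw.get("task", {})),
        _build("agent", AgentConfig, raw.get("agent", {})),
        _build("training", TrainConfig, raw.get("training", {})),
    )


def save_config(path, timing: TaskTiming | None = None, agent: AgentConfig | None = None,
                training: TrainConfig | None = None) -> None:
    doc = {
        "task": dataclasses.asdict(timing or TaskTiming()),
        "agent": dataclasses.asdict(agent or AgentConfig()),
        "training": dataclasses.asdict(training or TrainConfig()),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
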