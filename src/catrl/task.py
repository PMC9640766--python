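"""Sequential paired-association task.

A trial presents one sample stimulus followed by two successive
two-alternative choices.  Six visual stimuli form two associative chains
(functional categories): the A1-group {A1, B1, C1} and the A2-group
{A2, B2, C2}.  Depending on the sequence order (ABC, BCA or CAB) the
sample is an A-, B- or C-type stimulus and the agent must pick the next
item of the sample's chain at each of the two decision periods.

The environment is deterministic given a :class:`TrialSpec`; the only
randomness is in condition sampling (balanced shuffled blocks of the
24 conditions).  Time is discretised in steps of ``dt`` ms; rewards are
credited one step after the action that earned them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CHANNELS",
    "ACTIONS",
    "SEQUENCE_ORDERS",
    "FIRST_STIMULI",
    "TaskTiming",
    "EventSchedule",
    "TrialSpec",
    "TrialState",
    "RewardOutcome",
    "TrialSampler",
    "build_schedule",
    "observe",
    "observation_matrix",
    "step",
    "all_trial_specs",
    "Environment",
    "trial_log_frame",
]

#: Input-channel names, in order.  A-type stimuli have a single identity
#: channel; B- and C-type stimuli have one channel per screen side.
CHANNELS = (
    "fixation",
    "A1", "A2",
    "B1_left", "B1_right", "B2_left", "B2_right",
    "C1_left", "C1_right", "C2_left", "C2_right",
)

N_CHANNELS = len(CHANNELS)
_CH = {name: i for i, name in enumerate(CHANNELS)}

#: Channel value carried by each stimulus type.
STIM_VALUE = {"A": 2.0, "B": 3.0, "C": 4.0}

ACTIONS = ("F", "L", "R")
SEQUENCE_ORDERS = ("ABC", "BCA", "CAB")

#: Stimulus letter presented first / second / third for each order.
_ROTATION = {"ABC": ("A", "B", "C"), "BCA": ("B", "C", "A"), "CAB": ("C", "A", "B")}

#: Canonical ordering of the six first-stimulus conditions used by the
#: analysis code: A1-group then A2-group.
FIRST_STIMULI = ("A1", "B1", "C1", "A2", "B2", "C2")

_PERIOD_NAMES = (
    "initial_fixation",
    "first_stimulus",
    "first_delay",
    "second_stimulus",
    "first_decision",
    "mid_fixation",
    "third_stimulus",
    "second_decision",
)


@dataclass(frozen=True)
class TaskTiming:
    """Durations (ms) of the trial periods and the discretisation step."""

    dt: float = 20.0
    initial_fixation: float = 600.0
    first_stimulus: float = 400.0
    first_delay: float = 500.0
    second_stimulus: float = 200.0
    first_decision: float = 100.0
    mid_fixation: float = 300.0
    third_stimulus: float = 200.0
    second_decision: float = 100.0

    def durations(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _PERIOD_NAMES}

    @property
    def total_ms(self) -> float:
        return float(sum(self.durations().values()))

    @property
    def n_time_points(self) -> int:
        """Time points t = 0 .. total/dt inclusive (121 at dt = 20 ms)."""
        return int(round(self.total_ms / self.dt)) + 1


@dataclass(frozen=True)
class EventSchedule:
    """Ordered task periods as half-open step ranges [start, stop)."""

    timing: TaskTiming
    periods: tuple[tuple[str, int, int], ...]

    @property
    def n_action_steps(self) -> int:
        return self.periods[-1][2]

    @property
    def n_time_points(self) -> int:
        return self.n_action_steps + 1

    def range(self, name: str) -> tuple[int, int]:
        for pname, a, b in self.periods:
            if pname == name:
                return a, b
        raise KeyError(name)

    def period_at(self, t: int) -> str:
        for pname, a, b in self.periods:
            if a <= t < b:
                return pname
        if t == self.n_action_steps:
            return "trial_end"
        raise IndexError(f"step {t} outside trial")


def build_schedule(timing: TaskTiming) -> EventSchedule:
    """Discretise the period durations into contiguous step ranges.

    Raises ``ValueError`` if any duration is not an integer multiple of
    ``dt``.
    """
    periods = []
    start = 0
    for name, dur in timing.durations().items():
        n, rem = divmod(dur, timing.dt)
        if rem:
            raise ValueError(
                f"period {name!r} duration {dur} ms is not divisible by dt={timing.dt} ms"
            )
        stop = start + int(n)
        periods.append((name, start, stop))
        start = stop
    return EventSchedule(timing=timing, periods=tuple(periods))


@dataclass(frozen=True)
class TrialSpec:
    """One trial's condition.

    ``pos1``/``pos2`` give the side ("left"/"right") of the *target*
    stimulus (the next item of the trial's own chain) in the first and
    second choice pair.
    """

    sequence_order: str
    group: int
    pos1: str
    pos2: str

    def __post_init__(self):
        if self.sequence_order not in SEQUENCE_ORDERS:
            raise ValueError(f"unknown sequence order {self.sequence_order!r}")
        if self.group not in (1, 2):
            raise ValueError("group must be 1 or 2")
        for p in (self.pos1, self.pos2):
            if p not in ("left", "right"):
                raise ValueError("positions must be 'left' or 'right'")

    @property
    def letters(self) -> tuple[str, str, str]:
        return _ROTATION[self.sequence_order]

    @property
    def stimuli(self) -> tuple[str, str, str]:
        """Sample, first-choice target, second-choice target."""
        return tuple(f"{letter}{self.group}" for letter in self.letters)

    @property
    def first_stimulus(self) -> str:
        return self.stimuli[0]

    @property
    def first_stimulus_index(self) -> int:
        return FIRST_STIMULI.index(self.first_stimulus)


def all_trial_specs() -> list[TrialSpec]:
    """The 24 distinct conditions (3 orders x 2 groups x 2 x 2 sides)."""
    return [
        TrialSpec(o, g, p1, p2)
        for o, g, p1, p2 in itertools.product(
            SEQUENCE_ORDERS, (1, 2), ("left", "right"), ("left", "right")
        )
    ]


class TrialSampler:
    """Balanced condition sampling in shuffled blocks of all 24 conditions.

    Every block of 24 consecutive draws contains each condition exactly
    once, in an order shuffled by ``rng``; 24 draws equal one parameter
    update, so each update sees all conditions.
    """

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._block: list[TrialSpec] = []

    def sample(self) -> TrialSpec:
        if not self._block:
            block = all_trial_specs()
            self.rng.shuffle(block)
            self._block = block
        return self._block.pop()

    def sample_block(self, n: int) -> list[TrialSpec]:
        return [self.sample() for _ in range(n)]


@dataclass
class TrialState:
    """Mutable per-trial progress of the environment."""

    t: int = 0
    alive: bool = True
    first_choice: str = "none"   # none / left / right
    second_choice: str = "none"
    first_correct: bool = False
    second_correct: bool = False


@dataclass(frozen=True)
class RewardOutcome:
    reward: float
    done: bool
    event: str


def _choice_pair_channels(letter: str, group: int, target_side: str) -> dict[str, float]:
    """Channels active while a choice pair of the given type is on screen.

    For B/C pairs both stimuli appear, each on its side channel.  The A
    pair has identity channels only; the active channel names the
    stimulus shown on the LEFT (see docs/methods.md for the rationale).
    """
    value = STIM_VALUE[letter]
    other = 2 if group == 1 else 1
    if letter == "A":
        left_stim = group if target_side == "left" else other
        return {f"A{left_stim}": value}
    if target_side == "left":
        return {f"{letter}{group}_left": value, f"{letter}{other}_right": value}
    return {f"{letter}{other}_left": value, f"{letter}{group}_right": value}


def _sample_channels(letter: str, group: int) -> dict[str, float]:
    value = STIM_VALUE[letter]
    if letter == "A":
        return {f"A{group}": value}
    return {f"{letter}{group}_left": value}


def observe(spec: TrialSpec, schedule: EventSchedule, state: TrialState) -> np.ndarray:
    """Observation vector (11 channels) at the state's current step."""
    u = np.zeros(N_CHANNELS)
    if not state.alive:
        return u
    u[_CH["fixation"]] = 1.0
    period = schedule.period_at(state.t)
    letters = spec.letters
    if period == "first_stimulus":
        chans = _sample_channels(letters[0], spec.group)
    elif period == "second_stimulus":
        chans = _choice_pair_channels(letters[1], spec.group, spec.pos1)
    elif period == "third_stimulus":
        chans = _choice_pair_channels(letters[2], spec.group, spec.pos2)
    else:
        chans = {}
    for name, value in chans.items():
        u[_CH[name]] = value
    return u


def observation_matrix(spec: TrialSpec, schedule: EventSchedule) -> np.ndarray:
    """Stacked observations for every action step of a full-length trial.

    Observations depend only on the schedule and the condition (the
    fixation spot stays on for the whole trial), so the full input
    sequence can be precomputed; termination merely truncates its use.
    """
    state = TrialState()
    rows = []
    for t in range(schedule.n_action_steps):
        state.t = t
        rows.append(observe(spec, schedule, state))
    return np.asarray(rows)


def step(
    spec: TrialSpec,
    schedule: EventSchedule,
    state: TrialState,
    action: str,
) -> tuple[TrialState, RewardOutcome]:
    """Advance the trial by one step given the agent's action.

    The first non-fixation action inside a decision window is the
    choice; later actions in that window are ignored for reward.  A
    decision window that expires with no choice yields -1 and ends the
    trial.  Any L/R outside the decision windows breaks fixation (-1,
    trial over).  Rewards are credited at t+1.
    """
    if action not in ACTIONS:
        raise ValueError(f"action must be one of {ACTIONS}, got {action!r}")
    if not state.alive:
        raise RuntimeError("step() called on a terminated trial")

    t = state.t
    period = schedule.period_at(t)
    new = TrialState(**vars(state))
    new.t = t + 1

    def out(reward, done, event):
        if done:
            new.alive = False
        elif new.t == schedule.n_action_steps:
            # final time point reached: terminal observation, no action
            new.alive = False
            if event == "none":
                event = "trial-end"
            done = True
        return new, RewardOutcome(reward=reward, done=done, event=event)

    if period == "first_decision":
        last = schedule.range("first_decision")[1] - 1
        if state.first_choice != "none":
            return out(0.0, False, "none")
        if action == "F":
            if t == last:
                return out(-1.0, True, "no-choice-1")
            return out(0.0, False, "ok-fixation")
        side = "left" if action == "L" else "right"
        new.first_choice = side
        if side == spec.pos1:
            new.first_correct = True
            return out(1.0, False, "correct-choice-1")
        return out(-1.0, True, "wrong-choice-1")

    if period == "second_decision":
        last = schedule.range("second_decision")[1] - 1
        if state.second_choice != "none":
            return out(0.0, False, "none")
        if action == "F":
            if t == last:
                return out(-1.0, True, "no-choice-2")
            return out(0.0, False, "ok-fixation")
        side = "left" if action == "L" else "right"
        new.second_choice = side
        if side == spec.pos2:
            new.second_correct = True
            return out(1.0, False, "correct-choice-2")
        return out(0.0, False, "wrong-choice-2")

    # fixation, stimulus and delay periods
    if action == "F":
        return out(0.0, False, "ok-fixation")
    return out(-1.0, True, "break-fixation")


class Environment:
    """Stateful single-trial wrapper around the functional task core."""

    def __init__(self, timing: TaskTiming | None = None, rng: np.random.Generator | None = None):
        self.timing = timing or TaskTiming()
        self.schedule = build_schedule(self.timing)
        self.sampler = TrialSampler(rng or np.random.default_rng())
        self.spec: TrialSpec | None = None
        self.state: TrialState | None = None

    def reset(self, spec: TrialSpec | None = None) -> np.ndarray:
        self.spec = spec or self.sampler.sample()
        self.state = TrialState()
        return observe(self.spec, self.schedule, self.state)

    def step(self, action: str) -> tuple[np.ndarray, float, bool, str]:
        self.state, outcome = step(self.spec, self.schedule, self.state, action)
        obs = observe(self.spec, self.schedule, self.state)
        return obs, outcome.reward, outcome.done, outcome.event


def trial_log_frame(records: list[dict]):
    """Trial logs as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    columns = [
        "trial", "sequence_order", "group", "pos1", "pos2",
        "first_choice", "second_choice", "return", "termination_step",
    ]
    return pd.DataFrame.from_records(records, columns=columns)
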