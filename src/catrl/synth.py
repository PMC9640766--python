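"""Synthetic firing-rate fixtures for the analysis pipeline.

Generates trial x time x neuron rate tensors with a prescribed
within-category (WCD) and between-category (BCD) response structure in
the first-stimulus window, so the index and significance machinery can
be exercised against known ground truth without training a network.

Construction per neuron: the six condition means are
``base +/- BCD/2 + offsets`` with within-group offsets ``(-d, 0, d)``,
``d = 3 * WCD / 4``; this yields exactly the requested WCD, and exactly
the requested BCD whenever ``BCD >= 1.5 * WCD`` (the symmetric offsets
then cancel in the between-group means).  Within-group offset order and
the group sign are randomised per neuron.  Independent Gaussian noise
of ``noise_sd`` is added per trial and time step, so with
``wcd = bcd = 0`` the six labels are exchangeable (the bootstrap null).

What this emulates: condition-tuned, temporally flat rates with i.i.d.
noise.  What it does not: temporal dynamics, rectification at zero,
trial-to-trial correlations, or rate-dependent noise of the trained
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyntheticPopulation", "generate_population", "save_population", "load_population"]


@dataclass
class SyntheticPopulation:
    rates: np.ndarray          # (n_trials, n_steps, n_neurons)
    condition: np.ndarray      # (n_trials,) first-stimulus index 0..5
    true_means: np.ndarray     # (n_neurons, 6) window means without noise
    window: tuple[int, int]    # first-stimulus analysis window (steps)
    params: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[2]

    def window_rates(self) -> np.ndarray:
        """Per-trial mean rate in the first-stimulus window (n_trials, N)."""
        a, b = self.window
        return self.rates[:, a:b, :].mean(axis=1)

    def rate_max(self) -> np.ndarray:
        return self.rates.max(axis=(0, 1))


def generate_population(
    n_neurons: int = 60,
    trials_per_condition: int = 20,
    wcd: float = 0.5,
    bcd: float = 1.5,
    noise_sd: float = 0.2,
    base_rate: float = 2.0,
    n_steps: int = 121,
    window: tuple[int, int] = (30, 50),
    rng: np.random.Generator | int | None = None,
    n_silent: int = 0,
) -> SyntheticPopulation:
    """Draw a synthetic population with the given WCD/BCD structure.

    Defaults give roughly the scale of a converged run: a few hundred
    analysed trials, baseline-level rates of order 1, and a clear
    between-category separation.  ``n_silent`` appends units that stay
    at exactly zero throughout (for taxonomy tests).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    d = 3.0 * wcd / 4.0
    offsets = np.array([-d, 0.0, d])
    true_means = np.empty((n_neurons, 6))
    for i in range(n_neurons):
        sign = rng.choice([-1.0, 1.0])
        g1 = base_rate + sign * bcd / 2.0 + rng.permutation(offsets)
        g2 = base_rate - sign * bcd / 2.0 + rng.permutation(offsets)
        true_means[i] = np.concatenate([g1, g2])

    n_trials = 6 * trials_per_condition
    condition = rng.permutation(np.repeat(np.arange(6), trials_per_condition))
    a, b = window
    rates = np.full((n_trials, n_steps, n_neurons), base_rate)
    rates[:, a:b, :] = true_means[:, condition].T[:, None, :]  # (n_trials, 1, N)
    if noise_sd > 0:
        rates = rates + rng.normal(0.0, noise_sd, size=rates.shape)
    if n_silent:
        rates = np.concatenate([rates, np.zeros((n_trials, n_steps, n_silent))], axis=2)
        true_means = np.concatenate([true_means, np.zeros((n_silent, 6))], axis=0)
    return SyntheticPopulation(
        rates=rates, condition=condition, true_means=true_means, window=window,
        params={"wcd": wcd, "bcd": bcd, "noise_sd": noise_sd, "base_rate": base_rate,
                "trials_per_condition": trials_per_condition, "n_silent": n_silent},
    )


def save_population(path, pop: SyntheticPopulation) -> None:
    np.savez(
        path,
        rates=pop.rates, condition=pop.condition, true_means=pop.true_means,
        window=np.asarray(pop.window),
        param_names=np.array(list(pop.params), dtype="U32"),
        param_values=np.array([float(v) for v in pop.params.values()]),
    )


def load_population(path) -> SyntheticPopulation:
    with np.load(path) as data:
        params = dict(zip(data["param_names"].tolist(),
                          data["param_values"].tolist()))
        return SyntheticPopulation(
            rates=data["rates"], condition=data["condition"],
            true_means=data["true_means"], window=tuple(data["window"].tolist()),
            params=params,
        )
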