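# catrl — category learning in a recurrent network trained by reinforcement

`catrl` asks how functional categories — groups of arbitrary stimuli
that share associations, not appearance — can emerge in a neural
circuit that only ever receives reward feedback. It implements a deep
reinforcement-learning model of the primate prefrontal cortex
performing a **sequential paired-association task**, together with the
neuron-level analyses used to characterise what the trained units
encode. It is written for computational neuroscientists who want to
train the model end-to-end, reproduce the emergence of stimulus-coding
and category-coding units, or reuse the analysis suite on their own
trial × neuron × time recordings.

## The model

Two continuous-time gated recurrent rate networks interact:

* a **policy network** (actor): 11 task input channels → 150
  sparsely connected recurrent units (p₀ = 0.2 input, p₁ = 0.1
  recurrent) → softmax over the actions {fixate, left, right};
* a **value network** (critic): the policy layer's 150 rates plus the
  3 action-layer activities → 100 densely connected recurrent units →
  a scalar reward prediction v.

Each unit follows gated leaky-integration dynamics with process noise

    h(t) = (1 − ηφ(t)) h(t−1) + ηφ(t) [W_rec'(ψ(t)∘x(t−1)) + W_in'u(t) + b + ξ(t)],
    x(t) = [h(t)]⁺,   η = Δt/τ = 0.2,

and the agent is trained by policy-gradient actor-critic: the policy
maximises the expected episode return R = Σₜ r_{t+1} through the
REINFORCE gradient Σₜ ∇log π(aₜ|uₜ)·Υₜ with advantage Υₜ = Rₙ − b,
while the critic minimises the per-trial mean squared prediction error.
Updates happen every 24 trials; every 50 updates an 800-trial test
block with frozen parameters measures the correct-trial rate, and
training stops at 98%.

In the task, six stimuli form two associative chains {A1→B1→C1} and
{A2→B2→C2}. A trial presents a sample, then two successive
two-alternative choices: the agent must pick the next item of the
sample's own chain each time (+1 per correct choice, −1 for breaking
fixation or a wrong first choice). The chain membership is the
functional category.

After training, each unit's six first-stimulus condition means
x_{A1},…,x_{C2} yield

* **category index** CI = (BCD − WCD)/(BCD + WCD), the contrast of
  between- vs within-chain mean absolute rate differences, and
* **stimulus index** SI, the mean over chains of (max−min)/(max+min),

with CI significance assessed by a 500-shuffle permutation (bootstrap)
test. Non-silent units split into **category-neurons** (significant CI)
and **stimulus-neurons** (the rest).

## Worked example

```python
import numpy as np
from catrl import analysis, synth

# a synthetic population with a known category structure
pop = synth.generate_population(
    n_neurons=40, trials_per_condition=20,
    wcd=0.3, bcd=1.5, noise_sd=0.3, rng=0, n_silent=5,
)
rng = np.random.default_rng(1)
table = analysis.classify_neurons(
    pop.window_rates(), pop.condition, pop.rate_max(), rng)
print(analysis.population_summary(table))
```

prints

```
{'n_silent': 5, 'n_category': 40, 'n_stimulus': 0,
 'mean_CI_category': 0.6671973669714546, 'mean_CI_stimulus': nan,
 'min_CI_category': 0.6447909176175058, 'mean_SI_category': 0.13103279141429533,
 'mean_SI_stimulus': nan}
```

— all 40 tuned units are detected as category-neurons, the 5 flat units
are silent, and the mean CI ≈ 0.667 recovers the construction value
(BCD − WCD)/(BCD + WCD) = (1.5 − 0.3)/(1.5 + 0.3) = 2/3 within sampling
error. Training the full model is one call (an hour-scale computation):

```python
from catrl.training import train
run = train(seed=1, progress=True)
print(run.converged, run.iterations, run.final_checkpoint.correct_rate)
```

or from the shell:

```
catrl train --seed 1 --out runs/seed1
catrl evaluate --checkpoint runs/seed1/checkpoint_final.npz --trials 800
catrl make-fixtures --neurons 60 --trials-per-condition 20 \
    --wcd 0.5 --bcd 1.5 --noise-sd 0.2 --seed 0 --out fixtures.npz
```

`catrl train` writes a checkpoint, a CSV training log, the per-neuron
index table (`neuron_indexes.csv`) and a JSON summary.

## Package layout

| module | contents |
| --- | --- |
| `catrl.task` | task timing, event schedule, observation encoding, reward logic, balanced condition sampling |
| `catrl.gru` | the gated recurrent layer: forward dynamics, sparsity masks, hand-written backpropagation through time |
| `catrl.agent` | policy and value networks, action sampling, checkpoints |
| `catrl.training` | batched rollouts, objectives and gradients, optimisers, the learn/test loop |
| `catrl.analysis` | rate tables, category/stimulus indexes, bootstrap significance, neuron taxonomy, connectivity split, index time courses, weight and action-coding analyses |
| `catrl.synth` | synthetic trial × time × neuron fixtures with prescribed WCD/BCD structure |
| `catrl.config` | YAML configuration round-trip |
| `catrl.plots` | quick-look figures |

See `docs/methods.md` for the full model description, the training
recipe and its rationale, and known limitations.
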