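"""Neuron-level analysis of the policy IIL.

Quantifies what each recurrent unit encodes after (and during) learning:

* **Category index (CI)** — normalised contrast between the mean
  absolute rate difference across the two associative groups (BCD) and
  within them (WCD): ``CI = (BCD - WCD) / (BCD + WCD)``, in [-1, 1].
  Positive CI means larger response differences across categories.
* **Stimulus index (SI)** — mean over the two groups of
  ``(max - min) / (max + min)`` of the three within-group rates, in
  [0, 1]; measures within-category discrimination.
* **Bootstrap significance** — trial-to-stimulus labels are shuffled
  500 times; the observed CI is significant (p < 0.05, two-tailed) when
  it falls in the top or bottom 2.5% of the shuffled CI distribution.
* **Taxonomy** — silent units (exactly zero rate on every analysed
  trial) are excluded; the rest are category-neurons (significant CI)
  or stimulus-neurons (non-significant CI).

All rates are taken from correct test trials, with each of the six
stimuli contributing only trials in which it was the *first* stimulus
of its sequence (each stimulus is first in exactly one order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task import FIRST_STIMULI

__all__ = [
    "RateTable",
    "CategoryIndexResult",
    "StimulusIndexResult",
    "mean_rates",
    "category_index",
    "stimulus_index",
    "bootstrap_significance",
    "classify_neurons",
    "connectivity_split",
    "index_timecourse",
    "weight_analyses",
    "action_coding_classes",
    "population_summary",
]

_G1 = (0, 1, 2)  # A1, B1, C1
_G2 = (3, 4, 5)  # A2, B2, C2
_WITHIN_PAIRS = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
_BETWEEN_PAIRS = [(i, j) for i in _G1 for j in _G2]


@dataclass
class RateTable:
    """Mean rate per neuron per first-stimulus condition per window."""

    means: dict[str, np.ndarray]     # window -> (6, N)
    trial_counts: np.ndarray         # (6,)
    windows: dict[str, tuple[int, int]]

    def condition_means(self, window: str) -> np.ndarray:
        """(N, 6) array in the order A1, B1, C1, A2, B2, C2."""
        return self.means[window].T


def mean_rates(
    rates: np.ndarray,
    condition: np.ndarray,
    windows: dict[str, tuple[int, int]],
) -> RateTable:
    """Trial-averaged window rates per first-stimulus condition.

    ``rates`` is (n_trials, n_steps, n_neurons); ``condition`` gives the
    first-stimulus index (0..5) of each trial.  Rates are averaged over
    the window steps, then over trials of each condition.  A condition
    with no trials is flagged with NaN means (downstream index code
    excludes such neurons).
    """
    rates = np.asarray(rates)
    condition = np.asarray(condition)
    n_neurons = rates.shape[2]
    counts = np.array([(condition == c).sum() for c in range(6)])
    means = {}
    for name, (a, b) in windows.items():
        table = np.full((6, n_neurons), np.nan)
        win = rates[:, a:b, :].mean(axis=1)
        for c in range(6):
            sel = condition == c
            if sel.any():
                table[c] = win[sel].mean(axis=0)
        means[name] = table
    return RateTable(means=means, trial_counts=counts, windows=windows)


def category_index(means: np.ndarray) -> np.ndarray:
    """CI = (BCD - WCD) / (BCD + WCD) from six condition means.

    ``means`` is (..., 6) ordered A1, B1, C1, A2, B2, C2.  WCD averages
    the six within-group absolute differences, BCD the nine
    between-group ones.  NaN where BCD + WCD == 0 (all means equal) or
    any mean is missing.
    """
    m = np.asarray(means, dtype=float)
    wcd = sum(np.abs(m[..., i] - m[..., j]) for i, j in _WITHIN_PAIRS) / 6.0
    bcd = sum(np.abs(m[..., i] - m[..., j]) for i, j in _BETWEEN_PAIRS) / 9.0
    denom = bcd + wcd
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, (bcd - wcd) / np.where(denom > 0, denom, 1.0), np.nan)
    return ci


def category_index_parts(means: np.ndarray) -> dict[str, np.ndarray]:
    """WCD, BCD and the per-group difference sums alongside the CI."""
    m = np.asarray(means, dtype=float)
    fd_a1 = np.abs(m[..., 0] - m[..., 1]) + np.abs(m[..., 0] - m[..., 2]) + np.abs(m[..., 1] - m[..., 2])
    fd_a2 = np.abs(m[..., 3] - m[..., 4]) + np.abs(m[..., 3] - m[..., 5]) + np.abs(m[..., 4] - m[..., 5])
    fd1 = sum(np.abs(m[..., 0] - m[..., j]) for j in _G2)
    fd2 = sum(np.abs(m[..., 1] - m[..., j]) for j in _G2)
    fd3 = sum(np.abs(m[..., 2] - m[..., j]) for j in _G2)
    wcd = (fd_a1 + fd_a2) / 6.0
    bcd = (fd1 + fd2 + fd3) / 9.0
    return {"FD_A1": fd_a1, "FD_A2": fd_a2, "FD1": fd1, "FD2": fd2, "FD3": fd3,
            "WCD": wcd, "BCD": bcd, "CI": category_index(m)}


@dataclass
class CategoryIndexResult:
    ci: float
    wcd: float
    bcd: float
    p: float | None = None
    significant: bool | None = None


@dataclass
class StimulusIndexResult:
    si: float
    si_a1: float
    si_a2: float


def stimulus_index(means: np.ndarray) -> np.ndarray:
    """SI = mean of the two per-group (max-min)/(max+min) contrasts.

    NaN where a group's max + min is zero (that component undefined).
    """
    m = np.asarray(means, dtype=float)
    out = []
    for grp in (_G1, _G2):
        g = m[..., grp]
        hi, lo = g.max(axis=-1), g.min(axis=-1)
        denom = hi + lo
        with np.errstate(invalid="ignore", divide="ignore"):
            out.append(np.where(denom > 0, (hi - lo) / np.where(denom > 0, denom, 1.0), np.nan))
    return (out[0] + out[1]) / 2.0


def stimulus_index_parts(means: np.ndarray) -> StimulusIndexResult:
    m = np.asarray(means, dtype=float)
    comps = []
    for grp in (_G1, _G2):
        g = m[..., grp]
        hi, lo = g.max(axis=-1), g.min(axis=-1)
        comps.append((hi - lo) / (hi + lo) if hi + lo > 0 else np.nan)
    return StimulusIndexResult(si=float(np.mean(comps)), si_a1=float(comps[0]),
                               si_a2=float(comps[1]))


def _condition_means_from_trials(trial_rates: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(..., n_trials) rates + labels -> (..., 6) per-condition means."""
    means = np.stack([trial_rates[..., labels == c].mean(axis=-1) for c in range(6)], axis=-1)
    return means


def bootstrap_significance(
    trial_rates: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    n_shuffles: int = 500,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffle-based significance of the category index.

    ``trial_rates`` is (n_trials, n_neurons) first-stimulus-period rates
    and ``labels`` the per-trial first-stimulus condition.  Labels are
    permuted uniformly (the same permutation applied to every neuron per
    shuffle); a shuffle whose CI is undefined (all shuffled means equal)
    contributes CI = 0.  Returns (ci, p, significant): the observed CI,
    the two-tailed empirical tail proportion, and the top/bottom-2.5%
    flag.
    """
    trial_rates = np.asarray(trial_rates, dtype=float)
    labels = np.asarray(labels)
    if trial_rates.ndim == 1:
        trial_rates = trial_rates[:, None]
    counts = np.bincount(labels, minlength=6)
    if (counts < 2).any():
        raise ValueError("bootstrap requires at least 2 trials per condition")
    obs = category_index(_condition_means_from_trials(trial_rates.T, labels))
    n_neurons = trial_rates.shape[1]
    shuffled = np.empty((n_shuffles, n_neurons))
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        ci = category_index(_condition_means_from_trials(trial_rates.T, perm))
        shuffled[s] = np.nan_to_num(ci, nan=0.0)
    with np.errstate(invalid="ignore"):
        frac_ge = (shuffled >= obs[None, :]).mean(axis=0)
        frac_le = (shuffled <= obs[None, :]).mean(axis=0)
    tail = alpha / 2.0
    significant = (frac_ge <= tail) | (frac_le <= tail)
    p = np.clip(2.0 * np.minimum(frac_ge, frac_le), 0.0, 1.0)
    undefined = np.isnan(obs)
    significant[undefined] = False
    p[undefined] = np.nan
    return obs, p, significant


def classify_neurons(
    first_stim_trial_rates: np.ndarray,
    labels: np.ndarray,
    rate_max: np.ndarray,
    rng: np.random.Generator,
    n_shuffles: int = 500,
    silent_tol: float = 0.0,
):
    """Per-neuron taxonomy: silent / stimulus-neuron / category-neuron.

    Silent units have (exactly, up to ``silent_tol``) zero rate at every
    step of every analysed trial.  Non-silent units are category-neurons
    when the bootstrap finds their CI significant, stimulus-neurons
    otherwise.  Returns a pandas DataFrame with CI, SI, p and class.
    """
    import pandas as pd

    ci, p, significant = bootstrap_significance(
        first_stim_trial_rates, labels, rng, n_shuffles=n_shuffles
    )
    means = _condition_means_from_trials(np.asarray(first_stim_trial_rates).T,
                                         np.asarray(labels))
    si = stimulus_index(means)
    silent = np.asarray(rate_max) <= silent_tol
    label = np.where(silent, "silent",
                     np.where(significant, "category-neuron", "stimulus-neuron"))
    # a unit whose CI is undefined (flat means) cannot be indexed
    label[np.isnan(ci) & ~silent] = "excluded"
    return pd.DataFrame({
        "neuron": np.arange(len(ci)),
        "class": label,
        "CI": ci,
        "SI": si,
        "p": p,
        "significant": significant,
        "silent": silent,
    })


def connectivity_split(M_in: np.ndarray, table=None) -> dict:
    """Direct vs indirect units by the input sparsity mask.

    A unit is *direct* when at least one input-layer connection onto it
    exists in ``M_in`` (n_inputs, n_units).  When a classification table
    is given, per-group CI/SI summaries and a two-sided Mann-Whitney U
    comparison of the category-neuron CIs are included.
    """
    direct = np.asarray(M_in).astype(bool).any(axis=0)
    out = {
        "direct": direct,
        "n_direct": int(direct.sum()),
        "n_indirect": int((~direct).sum()),
        "direct_fraction": float(direct.mean()),
    }
    if table is not None:
        tab = table.copy()
        tab["direct"] = direct[tab["neuron"].to_numpy()]
        cats = tab[tab["class"] == "category-neuron"]
        for name, sel in (("direct", cats["direct"]), ("indirect", ~cats["direct"])):
            grp = cats[sel]
            out[f"category_{name}"] = {
                "n": int(len(grp)),
                "mean_CI": float(grp["CI"].mean()) if len(grp) else float("nan"),
                "mean_SI": float(grp["SI"].mean()) if len(grp) else float("nan"),
            }
        a = cats[cats["direct"]]["CI"].to_numpy()
        b = cats[~cats["direct"]]["CI"].to_numpy()
        if len(a) and len(b):
            out["mannwhitney_CI_p"] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return out


def index_timecourse(checkpoints, table, periods=None):
    """CI and SI per neuron class across test stages and task periods.

    ``checkpoints`` supply per-stage ``period_means`` (window -> (6, N)
    condition means); class membership is fixed by the final-stage
    classification ``table``.  Returns a tidy DataFrame with one row per
    (stage, period, class).
    """
    import pandas as pd

    periods = periods or ("first_stimulus", "first_delay", "second_stimulus",
                          "second_delay", "third_stimulus")
    classes = {
        "category-neuron": table[table["class"] == "category-neuron"]["neuron"].to_numpy(),
        "stimulus-neuron": table[table["class"] == "stimulus-neuron"]["neuron"].to_numpy(),
    }
    rows = []
    for cp in checkpoints:
        if cp.period_means is None:
            continue
        for period in periods:
            means = cp.period_means[period].T  # (N, 6)
            ci = category_index(means)
            si = stimulus_index(means)
            for cls, idx in classes.items():
                if len(idx) == 0:
                    continue
                rows.append({
                    "iteration": cp.iteration,
                    "period": period,
                    "class": cls,
                    "mean_CI": float(np.nanmean(ci[idx])),
                    "mean_SI": float(np.nanmean(si[idx])),
                })
    return pd.DataFrame(rows)


def weight_analyses(
    initial_params,
    final_params,
    recording,
    table=None,
) -> dict:
    """Weight histograms and the activity-similarity vs weight-change scan.

    For every directed connected pair (j -> i) in the recurrent mask,
    the Pearson correlation between the two units' trial-averaged
    first-stimulus-period rate traces (concatenated over the six
    conditions) is paired with the training-induced weight change of
    that connection.  Constant traces make the correlation undefined;
    such pairs are skipped.
    """
    mask = initial_params.M_rec.astype(bool)
    if not np.array_equal(mask, final_params.M_rec.astype(bool)):
        raise ValueError("initial and final parameters have different masks")
    hists = {
        name: getattr(final_params, name)[mask]
        for name in ("W_rec", "W_rec_upd", "W_rec_res")
    }
    a, b = recording.windows["first_stimulus"]
    traces = recording.mean_traces[:, a:b, :]           # (6, Tw, N)
    flat = traces.transpose(2, 0, 1).reshape(traces.shape[2], -1)  # (N, 6*Tw)
    sd = flat.std(axis=1)
    centered = flat - flat.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = centered / np.where(sd > 0, sd * np.sqrt(flat.shape[1]), np.nan)[:, None]
    corr = normed @ normed.T                            # pairwise Pearson r
    dw = final_params.W_rec - initial_params.W_rec
    jj, ii = np.nonzero(mask)
    r_pairs = corr[jj, ii]
    dw_pairs = dw[jj, ii]
    valid = np.isfinite(r_pairs)

    def _overall(sel):
        r, d = r_pairs[sel], dw_pairs[sel]
        if len(r) < 2 or r.std() == 0 or d.std() == 0:
            return float("nan"), float("nan")
        res = stats.pearsonr(r, d)
        return float(res.statistic), float(res.pvalue)

    out = {
        "weight_histograms": hists,
        "pairs": {"pre": jj, "post": ii, "similarity": r_pairs, "weight_change": dw_pairs},
        "similarity_weight_corr": {},
    }
    subsets = {"all": valid}
    if table is not None:
        for cls, key in (("stimulus-neuron", "stimulus"), ("category-neuron", "category")):
            members = set(table[table["class"] == cls]["neuron"].to_numpy())
            inset = np.array([(j in members) and (i in members) for j, i in zip(jj, ii)])
            subsets[key] = valid & inset
    for key, sel in subsets.items():
        r, p = _overall(sel)
        out["similarity_weight_corr"][key] = {"r": r, "p": p, "n_pairs": int(sel.sum())}
    return out


def action_coding_classes(
    recording,
    rate_max: np.ndarray | None = None,
    alpha: float = 0.05,
    min_trials: int = 2,
):
    """Classify units by stimulus vs action coding.

    Two factors are tested on first-decision-period rates of correct
    trials: the chosen side (left vs right; Mann-Whitney rank-sum) and
    the first-stimulus identity (six levels; Kruskal-Wallis, the
    rank-sum generalisation).  Stimulus selectivity is additionally
    assessed on the first stimulus + delay periods.  Classes:

    * ``stimulus-only`` — stimulus-selective early, side-insensitive at
      the decision;
    * ``stimulus-action`` — stimulus-selective early and side-sensitive
      at the decision;
    * ``action-only`` — side-sensitive at the decision, stimulus-
      insensitive early;
    * ``unclassified`` — anything else (including too few trials).

    Silent units are excluded.
    """
    import pandas as pd

    early = recording.window_rates["stimulus_and_delay"]   # (n_trials, N)
    dec = recording.window_rates["first_decision"]
    side = recording.chosen_side
    cond = recording.condition
    n_neurons = early.shape[1]
    if rate_max is None:
        rate_max = recording.rate_max
    silent = np.asarray(rate_max) <= 0.0

    def _p_side(x):
        a, b = x[side == 0], x[side == 1]
        if len(a) < min_trials or len(b) < min_trials or np.ptp(x) == 0:
            return 1.0
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

    def _p_stim(x):
        groups = [x[cond == c] for c in range(6)]
        if any(len(g) < min_trials for g in groups) or np.ptp(x) == 0:
            return 1.0
        return float(stats.kruskal(*groups).pvalue)

    rows = []
    for i in range(n_neurons):
        if silent[i]:
            rows.append({"neuron": i, "action_class": "silent",
                         "p_side": np.nan, "p_stim_early": np.nan})
            continue
        p_side = _p_side(dec[:, i])
        p_early = _p_stim(early[:, i])
        side_sel = p_side < alpha
        stim_sel = p_early < alpha
        if stim_sel and side_sel:
            cls = "stimulus-action"
        elif stim_sel:
            cls = "stimulus-only"
        elif side_sel:
            cls = "action-only"
        else:
            cls = "unclassified"
        rows.append({"neuron": i, "action_class": cls,
                     "p_side": p_side, "p_stim_early": p_early})
    return pd.DataFrame(rows)


def population_summary(table) -> dict:
    """Counts and mean CI per class, the quantities reported per run."""
    cats = table[table["class"] == "category-neuron"]
    stims = table[table["class"] == "stimulus-neuron"]
    return {
        "n_silent": int((table["class"] == "silent").sum()),
        "n_category": int(len(cats)),
        "n_stimulus": int(len(stims)),
        "mean_CI_category": float(cats["CI"].mean()) if len(cats) else float("nan"),
        "mean_CI_stimulus": float(stims["CI"].mean()) if len(stims) else float("nan"),
        "min_CI_category": float(cats["CI"].min()) if len(cats) else float("nan"),
        "mean_SI_category": float(cats["SI"].mean()) if len(cats) else float("nan"),
        "mean_SI_stimulus": float(stims["SI"].mean()) if len(stims) else float("nan"),
    }
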