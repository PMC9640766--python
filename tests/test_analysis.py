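"""Category/stimulus indexes, bootstrap, taxonomy, connectivity, weights."""

import itertools

import numpy as np
import pytest

from catrl import analysis, synth
from catrl.analysis import (
    bootstrap_significance,
    category_index,
    category_index_parts,
    classify_neurons,
    connectivity_split,
    mean_rates,
    stimulus_index,
    weight_analyses,
)


def brute_force_ci(means):
    """Independent oracle: explicit loops over all stimulus pairs."""
    g1, g2 = [0, 1, 2], [3, 4, 5]
    within = []
    for grp in (g1, g2):
        for i, j in itertools.combinations(grp, 2):
            within.append(abs(means[i] - means[j]))
    between = [abs(means[i] - means[j]) for i in g1 for j in g2]
    wcd = sum(within) / 6.0
    bcd = sum(between) / 9.0
    if bcd + wcd == 0:
        return np.nan
    return (bcd - wcd) / (bcd + wcd)


def brute_force_si(means):
    out = []
    for grp in ([0, 1, 2], [3, 4, 5]):
        vals = [means[i] for i in grp]
        hi, lo = max(vals), min(vals)
        out.append((hi - lo) / (hi + lo) if hi + lo > 0 else np.nan)
    return (out[0] + out[1]) / 2.0


class TestCategoryIndex:
    def test_perfect_category_coding(self):
        assert category_index(np.array([1, 1, 1, 0, 0, 0.0])) == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # means (1..6): WCD = 4/3, BCD = 3, CI = 5/13
        parts = category_index_parts(np.array([1, 2, 3, 4, 5, 6.0]))
        assert parts["WCD"] == pytest.approx(4 / 3)
        assert parts["BCD"] == pytest.approx(3.0)
        assert parts["CI"] == pytest.approx(5 / 13)

    def test_group_swap_symmetry(self, rng):
        m = rng.random((100, 6))
        swapped = m[:, [3, 4, 5, 0, 1, 2]]
        assert np.allclose(category_index(m), category_index(swapped), equal_nan=True)

    def test_all_equal_means_undefined(self):
        assert np.isnan(category_index(np.array([2.0] * 6)))

    def test_matches_brute_force_oracle(self, rng):
        tables = rng.gamma(2.0, 1.0, size=(1000, 6))
        ci = category_index(tables)
        oracle = np.array([brute_force_ci(row) for row in tables])
        assert np.max(np.abs(ci - oracle)) < 1e-12

    def test_range(self, rng):
        tables = rng.gamma(2.0, 1.0, size=(1000, 6))
        ci = category_index(tables)
        assert np.all(ci >= -1.0 - 1e-15) and np.all(ci <= 1.0 + 1e-15)


class TestStimulusIndex:
    def test_no_within_group_difference(self):
        assert stimulus_index(np.array([1, 1, 1, 2, 2, 2.0])) == pytest.approx(0.0)

    def test_hand_computed_case(self):
        # A1-group (1,2,3): SI=0.5; A2-group (2,2,2): SI=0 -> mean 0.25
        assert stimulus_index(np.array([1, 2, 3, 2, 2, 2.0])) == pytest.approx(0.25)

    def test_scale_invariance(self, rng):
        m = rng.random((200, 6)) + 0.1
        assert np.allclose(stimulus_index(m), stimulus_index(10 * m))

    def test_matches_brute_force_oracle(self, rng):
        tables = rng.gamma(2.0, 1.0, size=(1000, 6))
        si = stimulus_index(tables)
        oracle = np.array([brute_force_si(row) for row in tables])
        assert np.max(np.abs(si - oracle)) < 1e-12

    def test_range(self, rng):
        tables = rng.gamma(2.0, 1.0, size=(1000, 6))
        si = stimulus_index(tables)
        assert np.all(si >= 0.0) and np.all(si <= 1.0 + 1e-15)


class TestMeanRates:
    def test_constant_rates(self):
        rates = np.full((24, 50, 3), 3.0)
        cond = np.tile(np.arange(6), 4)
        table = mean_rates(rates, cond, {"w": (10, 20)})
        assert np.allclose(table.means["w"], 3.0)
        assert np.array_equal(table.trial_counts, np.full(6, 4))

    def test_synthetic_roundtrip_noise_free(self):
        pop = synth.generate_population(
            n_neurons=10, trials_per_condition=3, wcd=0.8, bcd=2.0,
            noise_sd=0.0, rng=0,
        )
        table = mean_rates(pop.rates, pop.condition, {"first_stimulus": pop.window})
        assert np.allclose(table.condition_means("first_stimulus"), pop.true_means)

    def test_empty_condition_flagged_nan(self):
        rates = np.ones((5, 10, 2))
        cond = np.array([0, 1, 2, 3, 4])  # condition 5 missing
        table = mean_rates(rates, cond, {"w": (0, 10)})
        assert np.isnan(table.means["w"][5]).all()
        assert np.isfinite(table.means["w"][:5]).all()

    def test_window_step_count(self):
        # a [30, 50) window at dt=20 covers exactly 20 steps
        rates = np.zeros((6, 121, 1))
        rates[:, 30:50, 0] = 1.0
        cond = np.arange(6)
        table = mean_rates(rates, cond, {"w": (30, 50), "full": (0, 121)})
        assert np.allclose(table.means["w"], 1.0)
        assert np.allclose(table.means["full"], 20 / 121)


class TestBootstrap:
    def test_identical_trials_never_significant(self, rng):
        trials = np.ones((60, 5))
        labels = np.tile(np.arange(6), 10)
        ci, p, sig = bootstrap_significance(trials, labels, rng)
        assert not sig.any()

    def test_strong_effect_significant(self, rng):
        # between-group gap 10x the noise sd
        pop = synth.generate_population(
            n_neurons=20, trials_per_condition=20, wcd=0.0, bcd=1.0,
            noise_sd=0.1, rng=rng,
        )
        ci, p, sig = bootstrap_significance(pop.window_rates(), pop.condition, rng)
        assert sig.all()
        assert (ci > 0.5).all()

    def test_requires_two_trials_per_condition(self, rng):
        with pytest.raises(ValueError):
            bootstrap_significance(np.ones((6, 2)), np.arange(6), rng)

    def test_false_positive_rate_calibrated(self):
        """On exchangeable data the bootstrap rejects ~5% of neurons."""
        rng = np.random.default_rng(2024)
        pop = synth.generate_population(
            n_neurons=1000, trials_per_condition=10, wcd=0.0, bcd=0.0,
            noise_sd=0.5, rng=rng,
        )
        ci, p, sig = bootstrap_significance(pop.window_rates(), pop.condition, rng)
        assert sig.mean() == pytest.approx(0.05, abs=0.02)


class TestClassification:
    def test_taxonomy_on_constructed_population(self, rng):
        n_cat, n_stim, n_silent = 8, 8, 4
        cat = synth.generate_population(n_neurons=n_cat, trials_per_condition=15,
                                        wcd=0.1, bcd=2.0, noise_sd=0.15, rng=rng)
        stim = synth.generate_population(n_neurons=n_stim, trials_per_condition=15,
                                         wcd=1.2, bcd=0.3, noise_sd=0.6, rng=rng)
        rates = np.concatenate(
            [cat.rates, stim.rates[:, :, :],
             np.zeros((cat.rates.shape[0], cat.rates.shape[1], n_silent))], axis=2)
        # same trial labels for every neuron: reuse cat's conditions and
        # re-sort stim trials to match
        order = np.argsort(cat.condition, kind="stable")
        order2 = np.argsort(stim.condition, kind="stable")
        rates[:, :, n_cat:n_cat + n_stim] = stim.rates[order2][np.argsort(order, kind="stable")]
        window = cat.window
        first = rates[:, window[0]:window[1], :].mean(axis=1)
        table = classify_neurons(first, cat.condition, rates.max(axis=(0, 1)), rng)
        classes = table["class"].to_numpy()
        assert (classes[:n_cat] == "category-neuron").mean() > 0.7
        assert (classes[n_cat + n_stim:] == "silent").all()
        # stimulus-coding units should mostly fail the category bootstrap
        assert (classes[n_cat:n_cat + n_stim] == "category-neuron").mean() < 0.5

    def test_population_summary_orders_classes(self, rng):
        pop = synth.generate_population(n_neurons=30, trials_per_condition=15,
                                        wcd=0.3, bcd=1.5, noise_sd=0.3, rng=rng,
                                        n_silent=5)
        first = pop.window_rates()
        table = classify_neurons(first, pop.condition, pop.rate_max(), rng)
        summary = analysis.population_summary(table)
        assert summary["n_silent"] == 5
        if summary["n_category"] and summary["n_stimulus"]:
            assert summary["mean_CI_category"] > summary["mean_CI_stimulus"]


class TestConnectivity:
    def test_all_direct_when_dense(self):
        out = connectivity_split(np.ones((11, 20)))
        assert out["n_direct"] == 20 and out["n_indirect"] == 0

    def test_all_indirect_when_empty(self):
        out = connectivity_split(np.zeros((11, 20)))
        assert out["n_direct"] == 0 and out["direct_fraction"] == 0.0

    def test_expected_direct_fraction_sparse(self):
        # Bernoulli(0.2) over 11 inputs: P(direct) = 1 - 0.8^11 ~ 0.914
        rng = np.random.default_rng(8)
        M = (rng.random((11, 5000)) < 0.2).astype(float)
        out = connectivity_split(M)
        assert out["direct_fraction"] == pytest.approx(1 - 0.8 ** 11, abs=0.02)


class TestWeightAnalyses:
    def _recording(self, traces):
        from catrl.training import TestRecording
        n = traces.shape[2]
        return TestRecording(
            n_neurons=n, windows={"first_stimulus": (0, traces.shape[1])},
            mean_traces=traces, trial_counts=np.full(6, 10),
            window_rates={}, condition=np.zeros(1, int),
            chosen_side=np.zeros(1, int), rate_max=np.ones(n),
        )

    def test_zero_weight_change(self, rng):
        from catrl import gru
        cfg = gru.GruConfig(n_units=6, n_inputs=3, p_rec=0.8)
        params = gru.init_params(cfg, rng)
        traces = rng.random((6, 10, 6))
        out = weight_analyses(params, params.copy(), self._recording(traces))
        assert np.all(out["pairs"]["weight_change"] == 0)

    def test_known_pair_correlation_recovered(self, rng):
        from catrl import gru
        cfg = gru.GruConfig(n_units=2, n_inputs=2, p_rec=1.0)
        p0 = gru.init_params(cfg, rng)
        p1 = p0.copy()
        p1.W_rec += rng.normal(size=(2, 2))
        # construct two traces with exact Pearson correlation 0.8
        z1 = rng.standard_normal(60)
        z2 = rng.standard_normal(60)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = (z2 - z2.mean()) / z2.std()
        z2 = z2 - (z2 @ z1) / 60 * z1          # orthogonalize
        z2 = z2 / np.sqrt((z2 ** 2).mean())
        y = 0.8 * z1 + np.sqrt(1 - 0.64) * z2
        traces = np.stack([z1, y], axis=1).reshape(6, 10, 2)
        out = weight_analyses(p0, p1, self._recording(traces))
        pairs = out["pairs"]
        off_diag = pairs["similarity"][pairs["pre"] != pairs["post"]]
        assert np.allclose(off_diag, 0.8, atol=1e-12)
        # self-connections correlate perfectly with themselves
        diag = pairs["similarity"][pairs["pre"] == pairs["post"]]
        assert np.allclose(diag, 1.0, atol=1e-12)

    def test_mask_mismatch_rejected(self, rng):
        from catrl import gru
        cfg = gru.GruConfig(n_units=4, n_inputs=2, p_rec=0.5)
        p0 = gru.init_params(cfg, np.random.default_rng(0))
        p1 = gru.init_params(cfg, np.random.default_rng(99))
        traces = rng.random((6, 5, 4))
        with pytest.raises(ValueError):
            weight_analyses(p0, p1, self._recording(traces))


class TestActionCoding:
    def _recording(self, early, dec, cond, side, rate_max):
        from catrl.training import TestRecording
        n = early.shape[1]
        return TestRecording(
            n_neurons=n, windows={}, mean_traces=np.zeros((6, 1, n)),
            trial_counts=np.zeros(6, int),
            window_rates={"stimulus_and_delay": early, "first_decision": dec},
            condition=cond, chosen_side=side, rate_max=rate_max,
        )

    def test_fixture_classes(self, rng):
        n_trials = 240
        cond = np.tile(np.arange(6), 40)
        side = rng.integers(0, 2, n_trials)
        noise = lambda: rng.normal(1.0, 0.05, n_trials)
        # neuron 0: side-tuned at decision only; neuron 1: stimulus-tuned early
        # only; neuron 2: both; neuron 3: flat; neuron 4: silent
        early = np.stack([
            noise(), noise() + 0.5 * cond, noise() + 0.5 * cond, noise(),
            np.zeros(n_trials)], axis=1)
        dec = np.stack([
            noise() + side, noise(), noise() + side, noise(),
            np.zeros(n_trials)], axis=1)
        rate_max = np.array([1.0, 1, 1, 1, 0.0])
        table = analysis.action_coding_classes(
            self._recording(early, dec, cond, side, rate_max))
        assert list(table["action_class"]) == [
            "action-only", "stimulus-only", "stimulus-action", "unclassified",
            "silent",
        ]


class TestIndexTimecourse:
    def test_monotone_injected_growth_recovered(self, rng):
        import pandas as pd
        from catrl.training import Checkpoint

        neurons = np.arange(4)
        table = pd.DataFrame({
            "neuron": neurons,
            "class": ["category-neuron", "category-neuron",
                      "stimulus-neuron", "stimulus-neuron"],
        })
        base = np.array([1, 1, 1, 0, 0, 0.0])
        cps = []
        for k, scale in enumerate([0.2, 0.5, 0.9]):
            means = np.ones((6, 4)) + scale * base[:, None]
            cps.append(Checkpoint(
                iteration=50 * (k + 1), first_choice_rate=0, correct_rate=0,
                mean_reward=0, value_mse_choice2=0, policy_params=None,
                period_means={p: means for p in (
                    "first_stimulus", "first_delay", "second_stimulus",
                    "second_delay", "third_stimulus")},
            ))
        tc = analysis.index_timecourse(cps, table)
        cat = tc[(tc["class"] == "category-neuron") & (tc["period"] == "first_stimulus")]
        assert cat["mean_CI"].is_monotonic_increasing

    def test_identical_checkpoints_identical_indexes(self, rng):
        import pandas as pd
        from catrl.training import Checkpoint

        table = pd.DataFrame({"neuron": [0, 1], "class": ["category-neuron"] * 2})
        means = rng.random((6, 2)) + 0.5
        cp = lambda it: Checkpoint(
            iteration=it, first_choice_rate=0, correct_rate=0, mean_reward=0,
            value_mse_choice2=0, policy_params=None,
            period_means={p: means for p in (
                "first_stimulus", "first_delay", "second_stimulus",
                "second_delay", "third_stimulus")},
        )
        tc = analysis.index_timecourse([cp(50), cp(100)], table)
        pivot = tc[tc["period"] == "first_delay"]["mean_CI"].to_numpy()
        assert pivot[0] == pivot[1]
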