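"""Episodic task: schedules, trial mechanics, recall tables, plasticity boost."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from semnet.params import ModelParams, reduced_params
from semnet.protocol import (
    DEFAULT_ASSOCIATION_MAP, ExperimentConfig, build_schedule, per_context_recall,
    recall_table, run_trial, toggle_augmentation,
)


@pytest.fixture
def params():
    return ModelParams()


class TestConfig:
    def test_default_map_uses_each_context_once(self):
        cfg = ExperimentConfig()
        used = [c for ctxs in cfg.association_map.values() for c in ctxs]
        assert sorted(used) == list(range(10))
        assert sorted(len(v) for v in cfg.association_map.values()) == [1, 2, 3, 4]

    def test_reused_context_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(association_map={0: (1, 2), 1: (2,)})

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(variant="recognition")


class TestSchedule:
    def test_item_cued_structure(self, params):
        """Ten encoding epochs (one per pairing), then one cue per item."""
        cfg = ExperimentConfig(variant="item-cued", shuffle_encoding=False)
        sch = build_schedule(cfg, params)
        enc = [e for e in sch.epochs if e.phase == "encoding"]
        cues = [e for e in sch.epochs if e.phase == "cue"]
        assert len(enc) == 20  # item + context epoch per pairing
        assert len(sch.pairings) == 10
        assert len(cues) == 4
        assert all(e.duration == params.stimulation.t_stim for e in enc)
        assert all(e.rate == params.stimulation.r_stim for e in enc)
        assert all(e.duration == params.stimulation.t_cue for e in cues)

    def test_encoding_timing(self, params):
        """250 ms stimuli at a 500 ms interstimulus interval, test after 1 s."""
        cfg = ExperimentConfig(shuffle_encoding=False)
        sch = build_schedule(cfg, params)
        onsets = sorted({e.onset for e in sch.epochs if e.phase == "encoding"})
        st = params.stimulation
        assert onsets[0] == st.t_settle
        np.testing.assert_allclose(np.diff(onsets), st.t_stim + st.isi)
        assert sch.t_test_start == sch.t_encoding_end + st.t_delay

    def test_paired_patterns_stimulated_simultaneously(self, params):
        cfg = ExperimentConfig(shuffle_encoding=False)
        sch = build_schedule(cfg, params)
        for item, ctx, t0, _ in sch.pairings:
            nets = {(e.network, e.pattern) for e in sch.epochs
                    if e.phase == "encoding" and e.onset == t0}
            assert nets == {(0, item), (1, ctx)}

    def test_multi_cue_cues_every_context_of_top_item(self, params):
        cfg = ExperimentConfig(variant="multi-cue")
        sch = build_schedule(cfg, params)
        cue_epochs = [e for e in sch.epochs if e.phase == "cue"]
        top_ctxs = set(cfg.association_map[3])  # the 4-association item
        cued = {e.pattern for e in cue_epochs}
        assert top_ctxs <= cued
        # one scoring window per item; 4-association window spans its cue burst
        assert len(sch.cues) == 4
        w4 = [c for c in sch.cues if c.n_assoc == 4][0]
        assert w4.window[1] - w4.window[0] > params.stimulation.cue_window

    def test_shuffled_orders_differ_by_seed(self, params):
        cfg = ExperimentConfig()
        a = build_schedule(cfg, params, np.random.default_rng(1)).pairings
        b = build_schedule(cfg, params, np.random.default_rng(2)).pairings
        assert [p[:2] for p in a] != [p[:2] for p in b]

    def test_empty_association_map(self, params):
        cfg = ExperimentConfig(association_map={})
        sch = build_schedule(cfg, params)
        assert sch.pairings == []
        assert all(e.phase != "encoding" for e in sch.epochs)

    def test_unknown_pattern_rejected(self, params):
        cfg = ExperimentConfig(association_map={0: (15,)})
        with pytest.raises(ValueError, match="unknown patterns"):
            build_schedule(cfg, params)


class TestAugmentationToggle:
    def test_disable_with_compensation(self, params):
        new, cfg = toggle_augmentation(params, enabled=False, compensate=True)
        assert not new.stp.enabled
        assert cfg.stim_rate_factor > 1.0
        assert cfg.stim_g_factor > 1.0

    def test_reenable_without_compensation(self, params):
        new, cfg = toggle_augmentation(params, enabled=True, compensate=True)
        assert new.stp.enabled
        assert cfg.stim_rate_factor == 1.0


class TestRecallTables:
    def _trial_like(self, rows, seed=0):
        out = pd.DataFrame(
            rows, columns=["cue", "network", "pattern", "n_assoc", "outcome",
                           "recalled"],
        )
        t = type("T", (), {})()
        t.outcomes = out
        t.seed = seed
        return t

    def test_single_trial_bernoulli_sd_zero_or_binary(self):
        tr = self._trial_like([
            (0, 0, 0, 1, "remember", "2"), (1, 0, 1, 2, "miss", ""),
        ])
        table = recall_table([tr])
        assert set(table.recall) <= {0.0, 1.0}
        assert np.all(table.sd == 0.0)

    def test_rates_pool_across_trials(self):
        trials = [
            self._trial_like([(0, 0, 0, 1, "remember", "2")], seed=1),
            self._trial_like([(0, 0, 0, 1, "miss", "")], seed=2),
        ]
        table = recall_table(trials)
        assert table.loc[table.n_assoc == 1, "recall"].iloc[0] == 0.5
        assert table.loc[table.n_assoc == 1, "sd"].iloc[0] == pytest.approx(
            np.sqrt(0.25 / 2)
        )

    def test_per_context_decomposition(self):
        cfg = ExperimentConfig()
        trials = [
            self._trial_like([(0, 0, 0, 3, "remember", "0,4")], seed=1),
            self._trial_like([(0, 0, 0, 3, "remember", "4")], seed=2),
        ]
        df = per_context_recall(trials, item=0, config=cfg)
        rates = dict(zip(df.context, df.recall))
        assert rates[4] == 1.0 and rates[0] == 0.5 and rates[9] == 0.0


class TestTrialMechanics:
    """Full trials on a 2-HC network: mechanics only, not recall statistics."""

    @pytest.fixture(scope="class")
    def mini_trial(self, tiny_net):
        cfg = ExperimentConfig(
            variant="item-cued", rule="bcpnn",
            association_map={0: (0,), 1: (1, 2)}, shuffle_encoding=False,
        )
        return cfg, run_trial(tiny_net, cfg, seed=5)

    def test_raster_within_simulation_window(self, mini_trial):
        _, tr = mini_trial
        assert np.all((tr.spike_times >= 0)
                      & (tr.spike_times <= tr.schedule.duration))

    def test_fixed_seed_reproducible(self, tiny_net, mini_trial):
        cfg, tr = mini_trial
        tr2 = run_trial(tiny_net, cfg, seed=5)
        np.testing.assert_array_equal(tr.spike_times, tr2.spike_times)
        np.testing.assert_array_equal(tr.spike_neurons, tr2.spike_neurons)
        pd.testing.assert_frame_equal(tr.outcomes, tr2.outcomes)

    def test_snapshots_tagged_by_phase(self, mini_trial):
        _, tr = mini_trial
        assert set(tr.snapshots) == {"post_encoding", "end"}
        wa, wn = tr.snapshots["post_encoding"]
        assert wa.shape == wn.shape

    def test_encoded_pairings_learn_positive_weights(self, mini_trial):
        """Post-encoding slow-bank weights of trained pairings exceed the
        (zero-initialized) untrained background."""
        _, tr = mini_trial
        wa, wn = tr.snapshots["post_encoding"]
        assert np.percentile(wn, 99) > 0.02  # learned tail
        assert abs(np.median(wn)) < 0.01     # untrained mass near zero

    def test_boost_requires_encoded_pairing(self, tiny_net):
        cfg = ExperimentConfig(
            variant="preferential-retention",
            association_map={0: (0,)}, boost_pairing=(0, 5),
        )
        with pytest.raises(ValueError, match="encoded pairings"):
            run_trial(tiny_net, cfg, seed=1)


class TestIntrinsicExcitability:
    """Bias-current trends over association counts (shared 10-trial runs)."""

    def test_item_bias_increases_with_encoding_count(self, desk_net, bcpnn_trials):
        """Cells of items encoded in more contexts end with higher intrinsic
        excitability, while the mean associative weight decreases: the
        weight/bias trade-off of Bayesian learning."""
        cfg, trials = bcpnn_trials
        bias_by_count, weight_by_count = {}, {}
        from semnet.protocol import associative_weight_table

        for item, ctxs in cfg.association_map.items():
            cells = desk_net.pattern_cells(0, item)
            bias_by_count[len(ctxs)] = np.mean(
                [tr.bias_snapshots["post_encoding"][cells].mean()
                 for tr in trials]
            )
        wt = pd.concat(
            [associative_weight_table(desk_net, tr, cfg) for tr in trials]
        )
        for count, grp in wt.groupby("n_assoc"):
            weight_by_count[count] = grp["w_slow"].mean()

        counts = sorted(bias_by_count)
        biases = [bias_by_count[c] for c in counts]
        weights = [weight_by_count[c] for c in counts]
        assert np.all(np.diff(biases) > 0), f"bias not increasing: {biases}"
        assert np.all(np.diff(weights) < 0), f"weights not decreasing: {weights}"

    def test_context_bias_similar_across_conditions(self, desk_net, bcpnn_trials):
        """Every context is encoded exactly once, so context-cell bias does
        not depend on how many associations its item forms."""
        cfg, trials = bcpnn_trials
        bias_by_count = {}
        for item, ctxs in cfg.association_map.items():
            vals = []
            for ctx in ctxs:
                cells = desk_net.pattern_cells(1, ctx)
                vals.extend(tr.bias_snapshots["post_encoding"][cells].mean()
                            for tr in trials)
            bias_by_count[len(ctxs)] = np.mean(vals)
        vals = np.array(list(bias_by_count.values()))
        spread = (vals.max() - vals.min()) / abs(vals.mean())
        assert spread < 0.15, f"context bias varies with item count: {bias_by_count}"


class TestVariantMechanics:
    """Plasticity-modulation and multi-cue trial wiring on the small network."""

    def test_boost_trial_runs_and_modulates_selected_synapses(self, tiny_net):
        cfg = ExperimentConfig(
            variant="preferential-retention", rule="bcpnn",
            association_map={0: (0, 1), 1: (2,)}, boost_pairing=(0, 1),
            shuffle_encoding=False,
        )
        tr = run_trial(tiny_net, cfg, seed=8)
        assert len(tr.outcomes) == 2  # one cue per item
        assert set(tr.outcomes.outcome) <= {"remember", "know", "miss"}
        # boosted pairing's coactivation trace outgrows a comparable control
        from semnet.protocol import associative_weight_table

        wt = associative_weight_table(tiny_net, tr, cfg)
        assert len(wt[(wt.item == 0) & (wt.ctx == 1)]) > 0

    def test_multi_cue_trial_scores_one_window_per_item(self, tiny_net):
        cfg = ExperimentConfig(
            variant="multi-cue", rule="bcpnn",
            association_map={0: (0, 1), 1: (2,)}, shuffle_encoding=False,
        )
        tr = run_trial(tiny_net, cfg, seed=9)
        assert len(tr.outcomes) == 2
        # the high-association item's window covers its sequential cue burst
        w_multi = [c for c in tr.schedule.cues if c.n_assoc == 2][0]
        w_single = [c for c in tr.schedule.cues if c.n_assoc == 1][0]
        assert (w_multi.window[1] - w_multi.window[0]) > (
            w_single.window[1] - w_single.window[0]
        )
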