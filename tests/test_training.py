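"""Loss construction, metrics, folds and the training loop contracts."""

import dataclasses

import numpy as np
import pytest

from pvlnode.lnode import SurrogateConfig, pack_weights
from pvlnode.parameters import ParameterVector
from pvlnode.traces import CHANNELS, PVTrace, SimulationDataset
from pvlnode.training import (
    LossBreakdown,
    NormalizationStats,
    TrainingConfig,
    compute_norm_stats,
    default_search_grid,
    evaluate,
    hyper_search,
    kfold_split,
    loss,
    metrics,
    train,
)


def synthetic_trace(rng, n=40, T=0.8, lo=40.0, hi=140.0):
    t = np.arange(n) * (T / n)
    base = rng.uniform(lo, hi, 8)
    amp = rng.uniform(1, 20, 8)
    phase = rng.uniform(0, 2 * np.pi, 8)
    vals = base + amp * np.sin(2 * np.pi * t[:, None] / T + phase)
    vals += rng.normal(0, 0.3, vals.shape)
    return PVTrace(t, np.abs(vals) + 1.0, T, 0.1)


class TestNormStats:
    def test_range_arithmetic(self, reduced_space):
        """A channel spanning [40, 140] across the set gives z_norm = 100."""
        t = np.arange(20) * (0.8 / 20)
        lowv = np.full((20, 8), 40.0)
        highv = np.full((20, 8), 140.0)
        ds = SimulationDataset(reduced_space, [
            (reduced_space.reference_vector(), PVTrace(t, lowv, 0.8, 0.1)),
            (reduced_space.reference_vector(), PVTrace(t, highv, 0.8, 0.1)),
        ])
        st = compute_norm_stats(ds)
        assert np.allclose(st.z_norm, 100.0)

    def test_duplication_invariance(self, small_dataset):
        st1 = compute_norm_stats(small_dataset)
        doubled = SimulationDataset(small_dataset.space,
                                    small_dataset.records * 2)
        st2 = compute_norm_stats(doubled)
        for f in ("z_norm", "z_norm_diff", "z_norm_max", "z_norm_min"):
            assert np.array_equal(getattr(st1, f), getattr(st2, f))

    def test_split_hygiene(self, small_dataset):
        """Stats depend only on the training split."""
        tr = small_dataset.subset(range(6))
        st1 = compute_norm_stats(tr)
        st2 = compute_norm_stats(small_dataset.subset(range(6)))
        assert np.array_equal(st1.z_norm, st2.z_norm)

    def test_positive_entries_enforced(self):
        with pytest.raises(ValueError):
            NormalizationStats(np.zeros(8), np.ones(8), np.ones(8), np.ones(8))


class TestLoss:
    def stats(self):
        return NormalizationStats(*(np.full(8, v) for v in (100, 500, 50, 30.0)))

    def test_perfect_fit_all_terms_zero(self):
        rng = np.random.default_rng(0)
        tr = synthetic_trace(rng)
        br = loss(tr, tr, np.zeros(10), self.stats(), TrainingConfig(),
                  latent=np.zeros((tr.n_samples + 1, 2)))
        assert br.total == 0.0
        assert all(v == 0.0 for v in br.as_dict().values())

    def test_default_auxiliary_weights(self):
        cfg = TrainingConfig()
        assert (cfg.alpha, cfg.beta, cfg.gamma, cfg.eta) == (0.1, 0.1, 0.1, 0.1)

    def test_recomposition_exact(self):
        rng = np.random.default_rng(1)
        a, b = synthetic_trace(rng), synthetic_trace(rng)
        w = rng.standard_normal(30)
        br = loss(a, b, w, self.stats(), TrainingConfig(),
                  latent=rng.standard_normal((a.n_samples + 1, 3)), iota=0.01)
        al, be, ga, et, io = br.weights
        manual = (br.trace_term + al * br.derivative_term + be * br.max_term
                  + ga * br.min_term + et * br.latent_period_term
                  + io * br.l2_term)
        assert br.total == pytest.approx(manual, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        a = synthetic_trace(rng, n=40)
        b = synthetic_trace(rng, n=50)
        with pytest.raises(ValueError, match="grid"):
            loss(a, b, np.zeros(3), self.stats(), TrainingConfig())

    def test_l2_term_and_iota_monotonicity(self):
        """At fixed weights, increasing iota never decreases the weighted
        total and leaves the raw l2 term unchanged."""
        rng = np.random.default_rng(3)
        a, b = synthetic_trace(rng), synthetic_trace(rng)
        w = rng.standard_normal(25)
        br1 = loss(a, b, w, self.stats(), TrainingConfig(), iota=0.01)
        br2 = loss(a, b, w, self.stats(), TrainingConfig(), iota=0.02)
        assert br1.l2_term == br2.l2_term == pytest.approx(np.sum(w**2))
        assert br2.total >= br1.total


class TestMetrics:
    def wrap(self, series):
        """Embed a scalar series into channel 0 of an 8-channel trace."""
        n = len(series)
        t = np.arange(n) * (0.8 / n)
        vals = np.full((n, 8), 50.0)
        vals[:, 0] = np.asarray(series, float) + 10.0
        return PVTrace(t, vals, 0.8, 0.1)

    def test_hand_example(self):
        """obs [0,1,2,3] vs pred [0,1,2,4]: NRMSE = 0.5/3, R2 = 80."""
        m = metrics(self.wrap([0, 1, 2, 4]), self.wrap([0, 1, 2, 3]))
        assert m["p_LA"]["NRMSE"] == pytest.approx(0.5 / 3)
        assert m["p_LA"]["R2"] == pytest.approx(80.0)

    def test_perfect_prediction(self):
        tr = self.wrap([0, 1, 2, 3])
        m = metrics(tr, tr)
        assert m["p_LA"]["NRMSE"] == 0.0
        assert m["p_LA"]["R2"] == 100.0

    def test_mean_predictor_gives_zero_r2(self):
        obs = self.wrap([0, 1, 2, 3])
        m = metrics(self.wrap([1.5, 1.5, 1.5, 1.5]), obs)
        assert m["p_LA"]["R2"] == pytest.approx(0.0)

    def test_constant_observed_channel_flagged(self, caplog):
        obs = self.wrap([2, 2, 2, 2])
        with caplog.at_level("WARNING"):
            m = metrics(self.wrap([0, 1, 2, 3]), obs)
        assert np.isnan(m["p_LA"]["NRMSE"])
        assert any("constant" in r.message for r in caplog.records)


class TestKfold:
    def test_400_by_10_gives_folds_of_40(self):
        folds = kfold_split(400, 10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 40 for f in folds)

    def test_partition_property(self):
        folds = kfold_split(53, 7, seed=3)
        allidx = np.concatenate(folds)
        assert len(allidx) == 53
        assert len(np.unique(allidx)) == 53
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_degenerate_singletons(self):
        folds = kfold_split(5, 5, seed=1)
        assert sorted(len(f) for f in folds) == [1] * 5

    def test_n_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5, seed=0)

    def test_deterministic(self):
        a = kfold_split(20, 4, seed=9)
        b = kfold_split(20, 4, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestTrain:
    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset.subset(range(3))
        cfg = TrainingConfig(epochs=10, pretrain_epochs=50, lbfgs_polish=0,
                             seed=7, time_stride=4)
        m1, _ = train(ds, None, cfg, SurrogateConfig())
        m2, _ = train(ds, None, cfg, SurrogateConfig())
        assert np.array_equal(pack_weights(m1.weights), pack_weights(m2.weights))

    def test_config_echo_in_report(self, tiny_surrogate):
        _, report, _ = tiny_surrogate
        assert report.config.alpha == 0.1
        assert report.model_config.neurons_per_layer == 13
        assert report.seed == report.config.seed

    def test_overfit_single_record(self, small_dataset):
        """With a generous budget the model memorizes one record
        (total loss < 1e-3)."""
        ds = small_dataset.subset([0])
        cfg = TrainingConfig(epochs=600, pretrain_epochs=2500, seed=0,
                             learning_rate=1e-2, lbfgs_polish=900,
                             iota=0.0)
        model, report = train(ds, None, cfg, SurrogateConfig(l2_weight=0.0))
        final = min(c["total"] for c in report.curve)
        assert final < 1e-3

    def test_latent_initial_conditions_trained(self, small_dataset):
        ds = small_dataset.subset(range(3))
        cfg = TrainingConfig(epochs=15, pretrain_epochs=50, lbfgs_polish=0,
                             seed=2, time_stride=4)
        model, _ = train(ds, None, cfg, SurrogateConfig(n_latent=2))
        assert model.z0_latent.shape == (2,)
        assert np.any(model.z0_latent != 0.0)


class TestHyperSearch:
    """Selection logic, with the expensive inner training stubbed out."""

    @staticmethod
    def _patch(monkeypatch, cands, scores):
        from pvlnode import training as tr_mod

        mcfgs = [m for m, _ in cands]

        def fake_train(ds, valid, cfg, mcfg):
            return mcfg, None    # pass the config through as the "model"

        def fake_evaluate(model, ds):
            s = scores[mcfgs.index(model)]
            return ({c: s for c in CHANNELS}, {c: 100 - s for c in CHANNELS})

        monkeypatch.setattr(tr_mod, "train", fake_train)
        monkeypatch.setattr(tr_mod, "evaluate", fake_evaluate)

    def test_single_candidate_returned(self, small_dataset, monkeypatch):
        mcfg = SurrogateConfig(hidden_layers=2, neurons_per_layer=5)
        cands = [(mcfg, {})]
        self._patch(monkeypatch, cands, [0.5])
        best, _, table = hyper_search(small_dataset, cands, K=2, seed=0)
        assert best == mcfg
        assert len(table) == 1

    def test_dominating_candidate_wins(self, small_dataset, monkeypatch):
        cands = [(SurrogateConfig(neurons_per_layer=4 + i), {}) for i in range(3)]
        self._patch(monkeypatch, cands, [0.40, 0.10, 0.55])
        best, _, table = hyper_search(small_dataset, cands, K=2, seed=0)
        assert best.neurons_per_layer == 5
        assert int(table["mean_val_nrmse"].idxmin()) == 1

    def test_tie_breaks_toward_fewer_weights(self, small_dataset, monkeypatch):
        cands = [(SurrogateConfig(neurons_per_layer=20), {}),
                 (SurrogateConfig(neurons_per_layer=5), {})]
        self._patch(monkeypatch, cands, [0.3, 0.3])
        best, _, _ = hyper_search(small_dataset, cands, K=2, seed=0)
        assert best.neurons_per_layer == 5

    def test_empty_grid_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="empty"):
            hyper_search(small_dataset, [], K=2)

    def test_default_grid_contains_selected_architecture(self):
        assert any(
            m.hidden_layers == 3 and m.neurons_per_layer == 13
            and m.n_latent == 0
            for m, _ in default_search_grid()
        )
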