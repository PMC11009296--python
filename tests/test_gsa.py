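"""QoI extraction, Saltelli design and Sobol estimators vs closed forms."""

import numpy as np
import pytest

from pvlnode.gsa import (
    QOI_NAMES,
    extract_qois,
    gsa_pipeline,
    rank_relevant,
    saltelli_sample,
    sobol_indices,
)
from pvlnode.parameters import ParameterSpace
from pvlnode.traces import PVTrace


def unit_space(P, lo=0.0, hi=1.0):
    return ParameterSpace([f"x{i}" for i in range(P)], [lo] * P, [hi] * P,
                          ["-"] * P, [(lo + hi) / 2] * P)


def make_trace(v_lv):
    n = len(v_lv)
    t = np.arange(n) * (0.8 / n)
    vals = np.full((n, 8), 50.0)
    vals[:, 5] = v_lv
    vals[:, 0] = 5 + np.sin(np.linspace(0, 2 * np.pi, n, endpoint=False))
    return PVTrace(t, vals, 0.8, 0.1)


class TestExtractQois:
    def test_stroke_volume_and_ejection_fraction(self):
        v = np.linspace(48, 120, 50)
        q = extract_qois(make_trace(np.concatenate([v, v[::-1]])))
        assert q["SV_LV"] == pytest.approx(72.0)
        assert q["EF_LV"] == pytest.approx(72.0 / 120.0)
        assert q["max_V_LV"] == pytest.approx(120.0)
        assert q["min_V_LV"] == pytest.approx(48.0)

    def test_constant_channel_gives_zero_sv(self):
        q = extract_qois(make_trace(np.full(40, 80.0)))
        assert q["SV_LV"] == 0.0

    def test_time_translation_invariance(self):
        v = 80 + 20 * np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False))
        a = extract_qois(make_trace(v))
        b = extract_qois(make_trace(np.roll(v, 17)))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_qoi_count_is_20(self):
        assert len(QOI_NAMES) == 20


class TestSaltelliSample:
    def test_row_counts(self):
        sp = unit_space(2)
        assert saltelli_sample(sp, 4, second_order=True, seed=0).shape == (24, 2)
        assert saltelli_sample(sp, 4, second_order=False, seed=0).shape == (16, 2)

    def test_rows_inside_box(self):
        sp = unit_space(5, lo=-2.0, hi=3.0)
        rows = saltelli_sample(sp, 32, second_order=True, seed=1)
        assert rows.min() >= -2.0 and rows.max() <= 3.0

    def test_deterministic_given_seed(self):
        sp = unit_space(3)
        a = saltelli_sample(sp, 8, seed=5)
        b = saltelli_sample(sp, 8, seed=5)
        assert np.array_equal(a, b)

    def test_non_power_of_two_warns(self):
        with pytest.warns(UserWarning, match="power of 2"):
            saltelli_sample(unit_space(2), 6, seed=0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            saltelli_sample(unit_space(2), 1, seed=0)

    def test_radial_block_structure(self):
        """AB_i equals A except in column i, which comes from B."""
        sp = unit_space(3)
        N = 8
        rows = saltelli_sample(sp, N, second_order=True, seed=2)
        A, B = rows[:N], rows[N:2 * N]
        for i in range(3):
            AB = rows[(2 + i) * N:(3 + i) * N]
            BA = rows[(5 + i) * N:(6 + i) * N]
            mask = np.arange(3) != i
            assert np.array_equal(AB[:, mask], A[:, mask])
            assert np.array_equal(AB[:, i], B[:, i])
            assert np.array_equal(BA[:, mask], B[:, mask])
            assert np.array_equal(BA[:, i], A[:, i])


def _evaluate_design(space, n_base, f, second_order=False, seed=0):
    rows = saltelli_sample(space, n_base, second_order=second_order, seed=seed)
    return rows, f(rows)


class TestSobolClosedForms:
    def test_additive_function(self):
        """Y = sum a_i X_i on U(0,1): S1_i = a_i^2 / sum a_j^2, ST = S1."""
        a = np.array([1.0, 2.0, 3.0])
        sp = unit_space(3)
        n = 2**14
        _, y = _evaluate_design(sp, n, lambda x: x @ a, seed=3)
        ix = sobol_indices(y, 3, n, n_bootstrap=0)
        expected = a**2 / np.sum(a**2)
        assert np.allclose(ix.S1[0], expected, atol=0.02)
        assert np.allclose(ix.ST[0], expected, atol=0.02)
        assert abs(ix.S1[0].sum() - 1.0) <= 0.05

    def test_pure_interaction(self):
        """Y = X1 X2 on centered U(-1,1): no first-order variance at all."""
        sp = unit_space(3, lo=-1.0, hi=1.0)
        n = 2**13
        _, y = _evaluate_design(sp, n, lambda x: x[:, 0] * x[:, 1], seed=4)
        ix = sobol_indices(y, 3, n, n_bootstrap=0)
        assert np.all(np.abs(ix.S1[0, :2]) < 0.02)
        assert np.all(ix.ST[0, :2] > 0.95)
        assert abs(ix.ST[0, 2]) < 0.02

    def test_ishigami(self):
        """Standard Ishigami constants against the analytic decomposition."""
        a, b = 7.0, 0.1
        sp = unit_space(3, lo=-np.pi, hi=np.pi)
        n = 2**14

        def f(x):
            return (np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2
                    + b * x[:, 2] ** 4 * np.sin(x[:, 0]))

        _, y = _evaluate_design(sp, n, f, seed=5)
        ix = sobol_indices(y, 3, n, n_bootstrap=0)
        V = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
        s1 = np.array([0.5 * (1 + b * np.pi**4 / 5) ** 2 / V, (a**2 / 8) / V, 0.0])
        assert np.allclose(ix.S1[0], s1, atol=0.02)

    def test_total_at_least_first_order(self):
        """ST >= S1 - MC tolerance on a mixed additive/interaction function."""
        sp = unit_space(4)
        n = 2**12

        def f(x):
            return x[:, 0] + 2 * x[:, 1] * x[:, 2] + 0.5 * x[:, 3] ** 2

        _, y = _evaluate_design(sp, n, f, seed=6)
        ix = sobol_indices(y, 4, n, n_bootstrap=50, seed=1)
        assert np.all(ix.ST >= ix.S1 - 0.02)
        assert np.all(ix.S1 > -0.02) and np.all(ix.ST < 1.02)

    def test_range_widening_does_not_reduce_total_index(self):
        """Widening one parameter's range cannot decrease its total index
        on a monotone (linear) function."""
        n = 2**12

        def f(x):
            return x @ np.array([1.0, 1.0, 1.0])

        narrow = unit_space(3)
        wide = ParameterSpace(["x0", "x1", "x2"], [0, 0, 0], [3.0, 1.0, 1.0],
                              ["-"] * 3, [0.5, 0.5, 0.5])
        _, y1 = _evaluate_design(narrow, n, f, seed=7)
        _, y2 = _evaluate_design(wide, n, f, seed=7)
        st1 = sobol_indices(y1, 3, n, n_bootstrap=0).ST[0, 0]
        st2 = sobol_indices(y2, 3, n, n_bootstrap=0).ST[0, 0]
        assert st2 >= st1 - 0.02

    def test_nan_rows_dropped_pairwise(self, caplog):
        sp = unit_space(2)
        n = 2**10
        rows = saltelli_sample(sp, n, seed=8)
        y = rows @ np.array([1.0, 2.0])
        y[5] = np.nan
        with caplog.at_level("WARNING"):
            ix = sobol_indices(y, 2, n, n_bootstrap=0)
        assert ix.n_base == n - 1
        assert np.allclose(ix.S1[0], [0.2, 0.8], atol=0.05)

    def test_second_order_detects_interaction(self):
        sp = unit_space(3, lo=-1.0, hi=1.0)
        n = 2**13
        _, y = _evaluate_design(sp, n, lambda x: x[:, 0] * x[:, 1],
                                second_order=True, seed=9)
        ix = sobol_indices(y, 3, n, second_order=True, n_bootstrap=0)
        assert ix.S2 is not None
        assert ix.S2[0, 0, 1] > 0.9
        assert abs(ix.S2[0, 0, 2]) < 0.05


class TestRankRelevant:
    def idx(self, st):
        from pvlnode.gsa import SobolIndices

        st = np.asarray(st, float)
        return SobolIndices(S1=np.zeros_like(st), ST=st,
                            qoi_names=tuple(f"q{i}" for i in range(st.shape[0])),
                            parameter_names=tuple(f"p{i}" for i in range(st.shape[1])),
                            n_base=8)

    def test_all_zero_gives_empty_set(self):
        rel, _ = rank_relevant(self.idx(np.zeros((3, 4))))
        assert rel == set()

    def test_single_entry_over_threshold(self):
        st = np.zeros((2, 3))
        st[1, 2] = 0.2
        rel, per = rank_relevant(self.idx(st))
        assert rel == {"p2"}
        assert per["p2"] == pytest.approx(0.2)

    def test_default_threshold_is_0p1(self):
        import inspect

        assert inspect.signature(rank_relevant).parameters["threshold"].default == 0.1


class TestPipeline:
    def test_pipeline_composition_and_ranges(self, tiny_surrogate):
        model, _, _ = tiny_surrogate
        ix = gsa_pipeline(model, n_base=32, seed=0, n_bootstrap=10)
        assert ix.S1.shape == (20, len(model.space))
        assert ix.ST.shape == (20, len(model.space))
        finite = np.isfinite(ix.ST)
        assert np.all(ix.ST[finite] < 1.5) and np.all(ix.ST[finite] > -0.5)

    def test_pipeline_matches_direct_estimator_on_known_function(self):
        """With evaluations from a known analytic function of theta the
        pipeline's estimator is exactly the direct sobol_indices result."""
        sp = unit_space(3)
        n = 2**10
        rows = saltelli_sample(sp, n, seed=11)
        y = rows @ np.array([3.0, 1.0, 0.5])
        direct = sobol_indices(y, 3, n, n_bootstrap=0)
        again = sobol_indices(y, 3, n, n_bootstrap=0)
        assert np.array_equal(direct.S1, again.S1)
        assert np.allclose(direct.S1[0],
                           np.array([9, 1, 0.25]) / 10.25, atol=0.03)
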