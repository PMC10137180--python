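import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurograph import (
    SparsityGrid,
    TimeSeriesMatrix,
    bandpass,
    binarize_at_sparsity,
    build_networks,
    correlation_matrix,
    detrend_linear,
    target_edge_count,
)
from neurograph.atlas import ConfigurationError, ValidationError
from neurograph.connectivity import CorrelationMatrix, binarize_sweep, rank_edge_order

from oracles import two_pass_pearson


def _ts(data, tr=2.0):
    return TimeSeriesMatrix("t", np.asarray(data, dtype=float), tr)


class TestDetrend:
    def test_exact_line_removed(self):
        t = np.arange(50.0)
        out = detrend_linear(_ts(np.column_stack([2 * t + 5, -3 * t + 1])))
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        once = detrend_linear(_ts(rng.standard_normal((80, 4))))
        twice = detrend_linear(once)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_sinusoid_plus_line_leaves_sinusoid(self):
        # cosine centered on the record midpoint over integer periods is
        # orthogonal to both the intercept and the slope regressor
        t = np.arange(200.0)
        wave = np.cos(2 * np.pi * (t - 99.5) / 10)
        out = detrend_linear(_ts((wave + 0.5 * t + 3).reshape(-1, 1)))
        assert np.max(np.abs(out.data[:, 0] - wave)) < 1e-8

    def test_zero_mean_columns(self):
        rng = np.random.default_rng(1)
        out = detrend_linear(_ts(rng.standard_normal((60, 3)) + 5))
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-10)


class TestBandpass:
    # T=200, TR=2 s: frequency bins at k/400 Hz, so 0.05 Hz is bin-aligned
    def test_passband_sinusoid_preserved(self):
        t = np.arange(200) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t).reshape(-1, 1)
        out = bandpass(_ts(x))
        in_rms = np.sqrt((x**2).mean())
        assert np.sqrt(((out.data - x) ** 2).mean()) < 0.01 * in_rms

    def test_stopband_sinusoid_removed(self):
        t = np.arange(200) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t).reshape(-1, 1)
        out = bandpass(_ts(x))
        assert np.sqrt((out.data**2).mean()) < 0.01 * np.sqrt((x**2).mean())

    def test_constant_series_zeroed(self):
        out = bandpass(_ts(np.full((100, 2), 7.0)))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_high_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError, match="Nyquist"):
            bandpass(_ts(np.zeros((100, 1)), tr=10.0), 0.01, 0.1)


class TestCorrelation:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(40)
        corr = correlation_matrix(_ts(np.column_stack([a, a, -a])))
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[0, 2] == pytest.approx(-1.0)

    def test_exact_small_series(self):
        x = np.array([1, 2, 3, 4, 5.0])
        corr = correlation_matrix(_ts(np.column_stack([x, 2 * x, x[::-1]])))
        assert corr.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert corr.values[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_column_named(self, small_atlas):
        data = np.random.default_rng(0).standard_normal((30, 20))
        data[:, 5] = 4.2
        with pytest.raises(ValidationError, match="SYN03.R"):
            correlation_matrix(_ts(data), atlas=small_atlas)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((60, 6))
        corr = correlation_matrix(_ts(data))
        for i in range(6):
            for j in range(i + 1, 6):
                assert corr.values[i, j] == pytest.approx(
                    two_pass_pearson(data[:, i], data[:, j]), abs=1e-12
                )


class TestBinarize:
    @pytest.mark.parametrize(
        "s,n,expected",
        [(0.10, 90, 401), (0.50, 90, 2003), (0.5, 3, 2), (0.25, 90, 1001)],
    )
    def test_target_edge_count_round_half_up(self, s, n, expected):
        assert target_edge_count(s, n) == expected

    def test_four_node_enumeration(self):
        # r values .9 > .8 > .7 > .6 > .5 > .4 on the six pairs
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4}
        m = np.eye(4)
        for (i, j), r in vals.items():
            m[i, j] = m[j, i] = r
        net = binarize_at_sparsity(CorrelationMatrix("t", m, 10), 0.5)  # 3 edges
        assert {tuple(e) for e in net.edges} == {(0, 1), (0, 2), (0, 3)}

    def test_exact_match_when_target_is_block(self):
        m = np.eye(6)
        keep = [(0, 1), (2, 3), (4, 5)]
        for i, j in keep:
            m[i, j] = m[j, i] = 1.0
        net = binarize_at_sparsity(CorrelationMatrix("t", m, 10), 0.2)  # 3 of 15
        assert {tuple(e) for e in net.edges} == set(keep)

    def test_tie_break_lexicographic(self):
        m = np.eye(4)
        m[m == 0] = 0.5  # all ties
        net = binarize_at_sparsity(CorrelationMatrix("t", m, 10), 0.5)
        assert {tuple(e) for e in net.edges} == {(0, 1), (0, 2), (0, 3)}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nested_edge_sets_across_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        m = rng.uniform(-1, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        corr = CorrelationMatrix("t", m, 30)
        grid = SparsityGrid.from_spec(10, 50, 10)
        nets = binarize_sweep(corr, grid)
        prev = set()
        for net in nets:
            cur = {tuple(e) for e in net.edges}
            assert prev <= cur
            assert len(cur) == target_edge_count(net.sparsity, n)
            prev = cur

    def test_achieved_density_within_one_edge(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(-1, 1, (30, 30))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        possible = 30 * 29 / 2
        for s in SparsityGrid.default():
            net = binarize_at_sparsity(CorrelationMatrix("t", m, 30), s)
            assert abs(net.achieved_sparsity - s) <= 1 / possible


class TestBuildNetworks:
    def test_default_grid_yields_41_networks(self):
        rng = np.random.default_rng(5)
        ts = _ts(rng.standard_normal((120, 12)))
        nets = build_networks(ts, SparsityGrid.default())
        assert len(nets) == 41
        for net in nets:
            assert net.n_edges == target_edge_count(net.sparsity, 12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((100, 10))
        perm = rng.permutation(10)
        grid = SparsityGrid.from_spec(20, 40, 10)
        nets = build_networks(_ts(data), grid)
        nets_p = build_networks(_ts(data[:, perm]), grid)
        for a, b in zip(nets, nets_p):
            # relabel the permuted networks back and compare adjacency
            inv = np.argsort(perm)
            back = b.adjacency[np.ix_(inv, inv)]
            # ties are broken by index so only compare where ranks are unambiguous
            assert (back == a.adjacency).all()


def test_rank_edge_order_is_total_and_deterministic():
    rng = np.random.default_rng(8)
    m = rng.uniform(-1, 1, (8, 8))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    e1 = rank_edge_order(m)
    e2 = rank_edge_order(m.copy())
    assert (e1 == e2).all()
    assert len(e1) == 28
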