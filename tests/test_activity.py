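"""PSTHs, correlation matrices, TR series, and the simplex-level analyses."""

import numpy as np
import pandas as pd
import pytest

from flagtopo import (
    ContractError,
    DirectedGraph,
    SpikeTrainSet,
    ValidationError,
    active_simplex_enrichment,
    build_flag_complex,
    correlation_matrix,
    edge_participation_correlation,
    maximal_simplices,
    participation,
    position_pair_correlation,
    psth,
    tr_series,
)
from flagtopo.activity import (
    PSTHMatrix,
    read_spikes_csv,
    read_spikes_hdf5,
    write_spikes_csv,
    write_spikes_hdf5,
)

from _oracles import brute_force_tr_edges


def single_trial(trains, duration):
    return SpikeTrainSet([[np.asarray(t, dtype=float)] for t in trains], duration)


class TestSpikeTrainSet:
    def test_rejects_out_of_range_times(self):
        with pytest.raises(ValidationError):
            SpikeTrainSet([[np.array([5.0, 10.0])]], duration=10.0)

    def test_rejects_non_increasing(self):
        with pytest.raises(ValidationError):
            SpikeTrainSet([[np.array([5.0, 5.0])]], duration=10.0)

    def test_csv_roundtrip(self, tmp_path):
        spk = SpikeTrainSet(
            [[np.array([1.0, 5.0]), np.array([2.0])], [np.array([3.0]), np.empty(0)]],
            duration=10.0,
        )
        path = tmp_path / "spk.csv"
        write_spikes_csv(spk, path)
        back = read_spikes_csv(path, duration=10.0, n_neurons=2, n_trials=2)
        for j in range(2):
            for t in range(2):
                assert np.allclose(back.spikes[j][t], spk.spikes[j][t])

    def test_hdf5_roundtrip(self, tmp_path):
        spk = SpikeTrainSet([[np.array([1.0, 5.0])], [np.empty(0)]], duration=10.0)
        path = tmp_path / "spk.h5"
        write_spikes_hdf5(spk, path)
        back = read_spikes_hdf5(path)
        assert back.duration == 10.0
        assert np.allclose(back.spikes[0][0], [1.0, 5.0])


class TestPSTH:
    def test_bin_counts(self):
        spk = single_trial([[2.0, 7.0]], duration=10.0)
        p = psth(spk, bin_size=5.0)
        assert p.rates.shape == (1, 2)
        assert np.allclose(p.rates, [[1.0, 1.0]])

    def test_trial_mean(self):
        spk = SpikeTrainSet(
            [[np.empty(0), np.array([1.0, 2.0])]], duration=5.0
        )
        p = psth(spk, bin_size=5.0)
        assert np.allclose(p.rates, [[1.0]])

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        lam_hz, T = 20.0, 10_000.0
        times = np.sort(rng.uniform(0, T, rng.poisson(lam_hz * T / 1000)))
        spk = single_trial([np.unique(times)], duration=T)
        p = psth(spk, bin_size=25.0)
        expect = lam_hz * 25.0 / 1000.0
        se = np.sqrt(expect / p.rates.shape[1])
        assert abs(p.rates.mean() - expect) < 3 * se


class TestCorrelationMatrix:
    def test_identical_rows_fully_correlated(self):
        p = PSTHMatrix(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]), 25.0)
        r = correlation_matrix(p)
        assert np.allclose(r.R, 1.0)

    def test_perfect_anticorrelation(self):
        p = PSTHMatrix(np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]), 25.0)
        r = correlation_matrix(p)
        assert np.allclose(r.R[0, 1], -1.0)

    def test_zero_variance_rows_masked(self):
        p = PSTHMatrix(np.array([[1.0, 2.0], [5.0, 5.0]]), 25.0)
        r = correlation_matrix(p)
        assert list(r.valid_mask) == [True, False]
        assert np.isnan(r.R[0, 1]) and np.isnan(r.R[1, 1])

    def test_matches_textbook_covariance(self):
        rng = np.random.default_rng(3)
        rows = rng.random((5, 40))
        r = correlation_matrix(PSTHMatrix(rows, 25.0)).R
        for i in range(5):
            for j in range(5):
                ci = rows[i] - rows[i].mean()
                cj = rows[j] - rows[j].mean()
                expected = (ci * cj).sum() / np.sqrt((ci**2).sum() * (cj**2).sum())
                assert abs(r[i, j] - expected) < 1e-12

    def test_concatenation(self):
        a = PSTHMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]), 25.0)
        b = PSTHMatrix(np.array([[3.0, 4.0], [4.0, 3.0]]), 25.0)
        joint = correlation_matrix(a, concatenate=[b])
        manual = correlation_matrix(
            PSTHMatrix(np.array([[1.0, 2, 3, 4], [2.0, 1, 4, 3]]), 25.0)
        )
        assert np.allclose(joint.R, manual.R)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        r = correlation_matrix(PSTHMatrix(rng.random((8, 30)), 25.0)).R
        assert np.allclose(r, r.T)
        assert np.nanmax(np.abs(r)) <= 1 + 1e-12
        assert np.allclose(np.diag(r), 1.0)


class TestTRSeries:
    def test_transmission_within_window(self):
        g = DirectedGraph.from_edges(2, [(0, 1)])
        spk = single_trial([[2.0], [8.0]], duration=20.0)
        tr = tr_series(spk, g, dt1=5.0, dt2=10.0)
        assert tr.edge_active[0, 0]
        assert tr.edge_active.sum() == 1

    def test_no_structural_edge_means_inactive(self):
        g = DirectedGraph.from_edges(2, [(1, 0)])
        spk = single_trial([[2.0], [8.0]], duration=20.0)
        tr = tr_series(spk, g, dt1=5.0, dt2=10.0)
        assert not tr.edge_active.any()

    def test_gap_at_dt2_excluded(self):
        g = DirectedGraph.from_edges(2, [(0, 1)])
        spk = single_trial([[2.0], [12.0]], duration=20.0)
        tr = tr_series(spk, g, dt1=5.0, dt2=10.0)
        assert not tr.edge_active.any()
        # strictly inside the window does count
        spk2 = single_trial([[2.0], [11.9]], duration=20.0)
        assert tr_series(spk2, g, dt1=5.0, dt2=10.0).edge_active.any()

    def test_simultaneous_spike_excluded(self):
        g = DirectedGraph.from_edges(2, [(0, 1)])
        spk = single_trial([[2.0], [2.0]], duration=20.0)
        assert not tr_series(spk, g, dt1=5.0, dt2=10.0).edge_active.any()

    def test_multi_trial_rejected(self):
        g = DirectedGraph.from_edges(2, [(0, 1)])
        spk = SpikeTrainSet([[np.array([1.0])] * 2, [np.array([2.0])] * 2], 10.0)
        with pytest.raises(ContractError):
            tr_series(spk, g)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_spike_pair_oracle(self, seed):
        rng = np.random.default_rng(2000 + seed)
        n, T = 12, 200.0
        trains = [
            np.unique(rng.uniform(0, T, rng.poisson(8))) for _ in range(n)
        ]
        edges = [
            (i, j) for i in range(n) for j in range(n)
            if i != j and rng.random() < 0.3
        ]
        g = DirectedGraph.from_edges(n, edges)
        tr = tr_series(single_trial(trains, T), g, dt1=5.0, dt2=10.0)
        expected = brute_force_tr_edges(trains, g.edge_set(), 5.0, 10.0, tr.n_bins)
        got = {
            (b, tuple(e))
            for b in range(tr.n_bins)
            for e in tr.active_edges(b)
        }
        assert got == expected

    def test_subgraph_invariant(self):
        rng = np.random.default_rng(5)
        n, T = 10, 500.0
        trains = [np.unique(rng.uniform(0, T, 30)) for _ in range(n)]
        g = DirectedGraph.from_edges(
            n, [(i, j) for i in range(n) for j in range(n) if i != j and rng.random() < 0.2]
        )
        tr = tr_series(single_trial(trains, T), g)
        structural = g.edge_set()
        for b in range(tr.n_bins):
            assert {tuple(e) for e in tr.active_edges(b)} <= structural


class TestEnrichment:
    @pytest.fixture
    def triangle_chain(self):
        # two triangles sharing an edge
        return DirectedGraph.from_edges(
            4, [(0, 1), (1, 2), (0, 2), (1, 3), (2, 3)]
        )

    def test_full_activity_gives_fraction_one(self, triangle_chain):
        g = triangle_chain
        spk = single_trial([[1.0], [3.0], [5.0], [7.0]], duration=10.0)
        tr = tr_series(spk, g, dt1=10.0, dt2=10.0)
        df = active_simplex_enrichment(tr, g, dims=[2], n_random=3, seed=0)
        assert df.loc[0, "edge_fraction"] == 1.0
        assert df.loc[0, "simplex_fraction_dim2"] == 1.0

    def test_empty_activity_gives_zero(self, triangle_chain):
        g = triangle_chain
        spk = single_trial([[], [], [], []], duration=10.0)
        tr = tr_series(spk, g, dt1=10.0, dt2=10.0)
        df = active_simplex_enrichment(tr, g, dims=[2], n_random=3, seed=0)
        assert df.loc[0, "edge_fraction"] == 0.0
        assert df.loc[0, "simplex_fraction_dim2"] == 0.0


class TestParticipationCorrelation:
    @pytest.fixture
    def toy(self):
        g = DirectedGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)])
        table = build_flag_complex(g)
        prof = participation(table, g)
        return g, table, prof

    def test_constant_correlation_gives_constant_means(self, toy):
        g, table, prof = toy
        from flagtopo.activity import CorrelationMatrix

        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        r = CorrelationMatrix(R, np.ones(3, dtype=bool))
        df = edge_participation_correlation(r, prof, min_samples=1)
        assert np.allclose(df["mean_R"], 0.5)
        ppc = position_pair_correlation(r, maximal_simplices(table, g))
        assert np.allclose(ppc["mean_R"], 0.5)

    def test_toy_table_matches_direct_recomputation(self, toy):
        g, table, prof = toy
        from flagtopo.activity import CorrelationMatrix

        R = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.8], [0.4, 0.8, 1.0]])
        r = CorrelationMatrix(R, np.ones(3, dtype=bool))
        df = edge_participation_correlation(r, prof, min_samples=1)
        # single maximal simplex (0,1,2): all 3 edges have count 1 at dim 2
        row = df[(df.dimension == 2) & (df.n_maximal == 1)].iloc[0]
        assert row["n_edges"] == 3
        assert np.isclose(row["mean_R"], np.mean([0.2, 0.8, 0.4]))

    def test_dimension_one_pair_kinds_coincide(self):
        g = DirectedGraph.from_edges(2, [(0, 1)])
        from flagtopo.activity import CorrelationMatrix

        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        r = CorrelationMatrix(R, np.ones(2, dtype=bool))
        maxi = maximal_simplices(build_flag_complex(g), g)
        df = position_pair_correlation(r, maxi)
        assert len(df) == 3
        assert np.allclose(df["mean_R"], 0.3)
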