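import numpy as np
import pandas as pd
import pytest

from axistrace import (
    AxisWeights,
    GenomicBins,
    LoopConfig,
    background_ring,
    call_candidates,
    cluster_summits,
    contact_frequency,
    finalize_loops,
)
from axistrace.loop_caller import test_pair as loop_test_pair
from axistrace.loop_caller import call_loops
from axistrace.variance_field import VarianceField, VarianceCurve
from axistrace.synthetic import SimulationSpec, simulate_planted
from axistrace import build_field, center_traces

from conftest import make_dataset


def brute_force_ring(j, k, p, resolution, cfg):
    """Independent enumeration of the background ring definition."""
    lo = int(np.ceil(cfg.background_min_kb * 1000 / resolution))
    hi = int(np.floor(cfg.background_max_kb * 1000 / resolution))
    out = []
    for jp in range(p):
        for kp in range(jp + 1, p):
            if (jp, kp) == (j, k):
                continue
            cheb = max(abs(jp - j), abs(kp - k))
            if lo <= cheb <= hi and (kp - jp) >= lo:
                out.append((jp, kp))
    return sorted(out)


def uniform_field(p=60, v=1.0, c=10, resolution=25_000):
    """A constant normalized field for exact-arithmetic checks."""
    V = np.full((3, p, p), float(v))
    C = np.full((3, p, p), int(c), dtype=np.int64)
    for a in range(3):
        np.fill_diagonal(V[a], np.nan)
        np.fill_diagonal(C[a], 0)
    bins = GenomicBins(chrom="chrU", starts=np.arange(p, dtype=np.int64) * resolution, resolution=resolution)
    curve = VarianceCurve(s=np.array([resolution, p * resolution]), v=np.array([v, v]))
    return VarianceField(V=V, C=C, raw=V.copy(), filtered=V.copy(),
                         E_raw=[curve] * 3, E_filt=[curve] * 3, bins=bins)


class TestBackgroundRing:
    def test_interior_pair_has_24_entries_at_25kb(self, bins25):
        bj, bk = background_ring(10, 30, bins25)
        assert bj.size == 24
        assert sorted(zip(bj.tolist(), bk.tolist())) == brute_force_ring(10, 30, 60, 25_000, LoopConfig())

    def test_edge_pair_ring_is_truncated(self, bins25):
        bj, bk = background_ring(0, 4, bins25)
        interior = background_ring(10, 30, bins25)[0].size
        assert 0 < bj.size < interior
        assert sorted(zip(bj.tolist(), bk.tolist())) == brute_force_ring(0, 4, 60, 25_000, LoopConfig())

    def test_5kb_bins_scale_radii_to_5_to_10(self):
        bins = GenomicBins(chrom="chr1", starts=np.arange(100, dtype=np.int64) * 5000, resolution=5000)
        bj, bk = background_ring(40, 70, bins)
        cheb = np.maximum(np.abs(bj - 40), np.abs(bk - 70))
        assert cheb.min() == 5 and cheb.max() == 10

    def test_near_diagonal_ring_entries_excluded(self, bins25):
        bj, bk = background_ring(10, 14, bins25)
        assert np.all(bk - bj >= 1)
        assert sorted(zip(bj.tolist(), bk.tolist())) == brute_force_ring(10, 14, 60, 25_000, LoopConfig())


class TestTestPair:
    def test_pooled_background_variance_and_df(self):
        # V = {2.0 (C=3), 1.0 (C=5)} pools to (2*2 + 4*1)/6 = 4/3, df 6
        field = uniform_field(p=60)
        a = 0
        field.V[a][:, :] = np.nan
        field.C[a][:, :] = 0
        entries = [(9, 29, 2.0, 3), (11, 31, 1.0, 5)]
        for j, k, v, c in entries:
            field.V[a][j, k] = field.V[a][k, j] = v
            field.C[a][j, k] = field.C[a][k, j] = c
        jj = np.array([9, 11])
        kk = np.array([29, 31])
        pooled, df = field.pooled_variance(a, jj, kk)
        assert pooled == pytest.approx(4 / 3)
        assert df == 6

    def test_equal_variances_give_half(self):
        # equal tested and background dfs: 24 ring entries of df 3 pool to
        # df 72, so the tested entry gets C = 73
        field = uniform_field(c=4)
        field.C[:, 10, 30] = field.C[:, 30, 10] = 73
        w = AxisWeights.equal()
        row = loop_test_pair(field, w, 10, 30)
        for axis in "xyz":
            assert row[f"p_{axis}"] == pytest.approx(0.5, abs=1e-9)
        assert row["p"] == pytest.approx(0.5, abs=1e-9)

    def test_too_few_background_entries_untested(self):
        field = uniform_field()
        a_all = slice(None)
        # invalidate all but 2 ring entries on every axis
        bj, bk = background_ring(10, 30, field.bins)
        for j, k in list(zip(bj, bk))[:-2]:
            field.V[a_all, j, k] = np.nan
            field.V[a_all, k, j] = np.nan
        row = loop_test_pair(field, AxisWeights.equal(), 10, 30)
        assert np.isnan(row["p"])

    def test_low_count_entry_untested(self):
        field = uniform_field()
        field.C[:, 10, 30] = 2
        field.C[:, 30, 10] = 2
        row = loop_test_pair(field, AxisWeights.equal(), 10, 30)
        assert np.isnan(row["p"])


class TestClustering:
    def _calls(self, pairs_p):
        rows = []
        for (j, k), p in pairs_p.items():
            rows.append({"j": j, "k": k, "p": p, "fdr": 0.01, "is_candidate": True,
                         "cluster_id": -1, "is_summit": False})
        return pd.DataFrame(rows)

    def test_adjacent_candidates_share_cluster_min_p_summit(self, bins25):
        calls = cluster_summits(self._calls({(10, 20): 1e-6, (10, 21): 1e-3}), bins25)
        assert calls["cluster_id"].nunique() == 1
        assert calls.loc[calls["is_summit"], ["j", "k"]].values.tolist() == [[10, 20]]

    def test_distant_candidates_are_singletons(self, bins25):
        calls = cluster_summits(self._calls({(10, 20): 1e-4, (30, 40): 1e-4}), bins25)
        assert calls["cluster_id"].nunique() == 2
        assert calls["is_summit"].all()

    def test_chain_merges_transitively(self, bins25):
        # A-B and B-C within 50 Kb, A-C 100 Kb apart: one component
        calls = cluster_summits(self._calls({(10, 20): 1e-4, (10, 22): 1e-5, (10, 24): 1e-3}), bins25)
        assert calls["cluster_id"].nunique() == 1
        assert int(calls["is_summit"].sum()) == 1

    def test_tie_broken_lexicographically(self, bins25):
        calls = cluster_summits(self._calls({(10, 21): 1e-4, (10, 20): 1e-4}), bins25)
        assert calls.loc[calls["is_summit"], ["j", "k"]].values.tolist() == [[10, 20]]


class TestContactFrequency:
    def _ds(self, distances):
        n = len(distances)
        coords = np.zeros((n, 3, 3))
        coords[:, 1, 0] = distances  # distance realized along x between bins 0 and 1
        return make_dataset(coords)

    def test_counts_below_cutoff(self):
        ds = self._ds([300.0, 600.0, 400.0])
        assert contact_frequency(ds, 0, 1, 500.0) == pytest.approx(2 / 3)

    def test_all_contacts(self):
        ds = self._ds([10.0, 20.0])
        assert contact_frequency(ds, 0, 1, 500.0) == 1.0

    def test_zero_cutoff(self):
        ds = self._ds([10.0, 20.0])
        assert contact_frequency(ds, 0, 1, 0.0) == 0.0

    def test_no_coobserved_traces_nan(self):
        coords = np.zeros((1, 3, 3))
        coords[0, 1, :] = np.nan
        ds = make_dataset(coords)
        assert np.isnan(contact_frequency(ds, 0, 1, 500.0))


class TestFinalize:
    def _summit_frame(self, p, cluster_size, freq_field):
        rows = [{"j": 10, "k": 30, "p": p, "fdr": 1e-3, "is_candidate": True,
                 "cluster_id": 0, "is_summit": True, "contact_freq": np.nan, "is_final": False}]
        for extra in range(cluster_size - 1):
            rows.append({"j": 10, "k": 31 + extra, "p": p * 10, "fdr": 1e-3,
                         "is_candidate": True, "cluster_id": 0, "is_summit": False,
                         "contact_freq": np.nan, "is_final": False})
        return pd.DataFrame(rows), freq_field

    def _ds_with_freq(self, freq, n=100):
        coords = np.zeros((n, 60, 3))
        far = int(round(n * (1 - freq)))
        coords[:far, 30, 0] = 10_000.0  # beyond any contact cutoff
        return make_dataset(coords)

    def test_summit_above_p_cutoff_dropped(self):
        calls, _ = self._summit_frame(2e-5, 1, None)
        out = finalize_loops(calls, self._ds_with_freq(1.0))
        assert not out["is_final"].any()

    def test_singleton_low_frequency_dropped_with_filter(self):
        calls, _ = self._summit_frame(1e-6, 1, None)
        cfg = LoopConfig(apply_frequency_filter=True)
        out = finalize_loops(calls, self._ds_with_freq(0.45), cfg)
        assert not out["is_final"].any()

    def test_cluster_summit_kept_at_04_frequency(self):
        calls, _ = self._summit_frame(1e-6, 3, None)
        cfg = LoopConfig(apply_frequency_filter=True)
        out = finalize_loops(calls, self._ds_with_freq(0.40), cfg)
        assert bool(out.loc[0, "is_final"])

    def test_filter_off_keeps_low_frequency_summit(self):
        calls, _ = self._summit_frame(1e-6, 1, None)
        out = finalize_loops(calls, self._ds_with_freq(0.10))
        assert bool(out.loc[0, "is_final"])


class TestInvariances:
    def test_translation_and_reflection_leave_pvalues_unchanged(self):
        ds, _ = simulate_planted(SimulationSpec(n=80, p=30, missing_rate=0.05, seed=21))
        ds = center_traces(ds)
        w = AxisWeights.equal()
        base = call_candidates(build_field(ds), w)

        shifted = ds.coords + np.array([123.0, -77.0, 5.0])
        shifted[ds.missing] = np.nan
        ds_shift = center_traces(make_dataset(shifted))
        moved = call_candidates(build_field(ds_shift), w)
        np.testing.assert_allclose(base["p"], moved["p"], atol=1e-9)

        flipped = ds.coords.copy()
        flipped[:, :, 2] *= -1
        ds_flip = make_dataset(flipped, centered=True)
        mirror = call_candidates(build_field(ds_flip), w)
        np.testing.assert_allclose(base["p"], mirror["p"], atol=1e-9)

    def test_empty_field_returns_empty(self):
        field = uniform_field(p=4)  # too small for any 100-Kb-separated pair
        out = call_candidates(field, AxisWeights.equal())
        assert out.empty

    def test_full_pipeline_flags_are_consistent(self):
        ds, _ = simulate_planted(SimulationSpec(n=150, p=40, seed=22))
        ds = center_traces(ds)
        calls = call_loops(ds, build_field(ds), AxisWeights.equal())
        final = calls[calls["is_final"]]
        assert final["is_summit"].all()
        summits = calls[calls["is_summit"]]
        assert summits["is_candidate"].all()
        assert (calls.loc[calls["is_candidate"], "fdr"] < 0.1).all()
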