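import numpy as np
import pytest

from axistrace import build_field, center_traces, outlier_mask, robust_variance_matrix
from axistrace.synthetic import PlantedLoop, SimulationSpec, simulate_planted
from axistrace.variance_field import (
    GAUSSIAN_CONSISTENCY,
    VarianceCurve,
    expected_variance_curve,
    fit_variance_curve,
)

from conftest import make_dataset


def _diff_dataset(diffs, p=3):
    """Dataset whose (0, 1) x-differences across traces equal ``diffs``."""
    diffs = np.asarray(diffs, dtype=float)
    coords = np.zeros((diffs.size, p, 3))
    coords[:, 0, 0] = diffs
    return make_dataset(coords, centered=True)


class TestRobustVariance:
    def test_constant_differences_give_zero(self):
        ds = _diff_dataset([50.0] * 5)
        raw = robust_variance_matrix(ds, "x")
        assert raw[0, 1] == pytest.approx(0.0)

    def test_median_breakdown_hides_minority_spread(self):
        # d = (-100, 0, 100, 0, 0): median 0, squared deviations
        # (1e4, 0, 1e4, 0, 0), median 0 -> robust variance 0
        ds = _diff_dataset([-100.0, 0.0, 100.0, 0.0, 0.0])
        raw = robust_variance_matrix(ds, "x")
        assert raw[0, 1] == pytest.approx(0.0)

    def test_gaussian_consistency_constant(self):
        # Monte-Carlo oracle: the 2.1981 constant makes the median-based
        # value estimate the ordinary variance of Gaussian differences
        rng = np.random.default_rng(6)
        ds = _diff_dataset(rng.normal(scale=100.0, size=2000))
        raw = robust_variance_matrix(ds, "x")
        assert raw[0, 1] == pytest.approx(10_000.0, rel=0.10)

    def test_symmetry_and_nan_diagonal(self, small_centered_dataset):
        raw = robust_variance_matrix(small_centered_dataset, "y")
        np.testing.assert_array_equal(raw, raw.T)
        assert np.isnan(np.diag(raw)).all()

    def test_fewer_than_three_pairs_is_nan(self):
        ds = _diff_dataset([1.0, 2.0])
        raw = robust_variance_matrix(ds, "x")
        assert np.isnan(raw[0, 1])


class TestExpectedVarianceCurve:
    def test_linear_in_distance_recovered(self, bins25):
        p = bins25.p
        jj, kk = np.meshgrid(np.arange(p), np.arange(p), indexing="ij")
        mat = 2.0 * np.abs(jj - kk) * bins25.resolution
        mat = mat.astype(float)
        np.fill_diagonal(mat, np.nan)
        curve = expected_variance_curve(mat, bins25)
        interior = np.arange(5, 40) * bins25.resolution
        np.testing.assert_allclose(curve(interior), 2.0 * interior, rtol=0.05)

    def test_constant_input_gives_constant_curve(self, bins25):
        mat = np.full((bins25.p, bins25.p), 7_500.0)
        np.fill_diagonal(mat, np.nan)
        curve = expected_variance_curve(mat, bins25)
        np.testing.assert_allclose(curve(np.array([25e3, 500e3])), 7_500.0, rtol=1e-6)

    def test_single_distance_stratum_returns_its_mean(self):
        curve = fit_variance_curve(np.array([2.0, 4.0]), np.array([25e3, 25e3]))
        assert curve(25e3) == pytest.approx(3.0)

    def test_all_nan_raises(self, bins25):
        mat = np.full((bins25.p, bins25.p), np.nan)
        with pytest.raises(ValueError):
            expected_variance_curve(mat, bins25)

    def test_floor_keeps_curve_positive(self):
        curve = VarianceCurve(s=np.array([1e4, 2e4]), v=np.array([5.0, -10.0]))
        assert curve(1e5) == pytest.approx(curve.floor)


class TestOutlierMask:
    @pytest.mark.parametrize("d,kept", [(210.0, False), (199.0, True)])
    def test_four_sd_threshold(self, d, kept):
        # E(s) = 2500 nm^2 (sd 50): |d| <= 200 survives
        ds = _diff_dataset([d])
        curve = VarianceCurve(s=np.array([25e3, 50e3]), v=np.array([2500.0, 2500.0]))
        mask = outlier_mask(ds, "x", curve)
        assert bool(mask[0, 0, 1]) is kept

    def test_gaussian_removal_fraction(self):
        # expected removal 2*Phi(-4) ~ 6.33e-5 at one million differences
        rng = np.random.default_rng(7)
        ds = _diff_dataset(rng.normal(scale=50.0, size=1_000_000))
        curve = VarianceCurve(s=np.array([25e3, 50e3]), v=np.array([2500.0, 2500.0]))
        mask = outlier_mask(ds, "x", curve)
        removed = 1.0 - mask[:, 0, 1].mean()
        assert removed == pytest.approx(6.33e-5, rel=0.5)


class TestBuildField:
    def test_noise_only_field_is_flat_at_one(self):
        ds, _ = simulate_planted(SimulationSpec(n=1000, p=30, scale=1e-6, missing_rate=0.0, seed=8))
        field = build_field(center_traces(ds))
        offsets = np.abs(np.subtract.outer(np.arange(30), np.arange(30)))
        for a in range(3):
            for d in (1, 5, 14, 25):
                stratum = field.V[a][offsets == d]
                assert np.nanmean(stratum) == pytest.approx(1.0, abs=0.05)

    def test_planted_proximity_pair_is_row_minimum(self):
        spec = SimulationSpec(
            n=1500, p=30, missing_rate=0.0,
            loops=[PlantedLoop(5, 20, 0.5)], seed=9,
        )
        ds, _ = simulate_planted(spec)
        field = build_field(center_traces(ds))
        for a in range(3):
            row = field.V[a][5].copy()
            assert np.nanargmin(row) == 20
            assert field.V[a][5, 20] == pytest.approx(0.5, abs=0.15)

    def test_wild_outlier_barely_moves_the_field(self, small_centered_dataset):
        ds = small_centered_dataset
        clean = build_field(ds)
        coords = ds.coords.copy()
        sd = np.sqrt(clean.E_raw[0](ds.bins.resolution * 3))
        coords[0, 3, 0] = coords[0, 0, 0] - 20.0 * sd  # 20-SD difference at (0, 3)
        dirty = build_field(make_dataset(coords, centered=True))
        v0, v1 = clean.V[0][0, 3], dirty.V[0][0, 3]
        assert abs(v1 - v0) / v0 < 0.05

    def test_symmetry_and_counts(self, small_centered_dataset):
        field = build_field(small_centered_dataset)
        for a in range(3):
            np.testing.assert_array_equal(field.V[a], field.V[a].T)
            np.testing.assert_array_equal(field.C[a], field.C[a].T)
            assert field.C[a].max() <= small_centered_dataset.n
            ok = field.C[a] >= 2
            assert np.isfinite(field.V[a][ok]).all()

    def test_renormalized_field_refits_to_one(self, small_centered_dataset):
        # fitting a second curve to the normalized entries must give ~1
        field = build_field(small_centered_dataset)
        p = field.p
        ju, ku = np.triu_indices(p, k=1)
        s = field.bins.genomic_distance(ju, ku)
        for a in range(3):
            curve = fit_variance_curve(field.V[a][ju, ku], s.astype(float))
            interior = np.linspace(s.min() * 2, s.max() * 0.8, 20)
            np.testing.assert_allclose(curve(interior), 1.0, atol=0.10)


class TestSufficientStatistics:
    def test_pooled_variance_matches_brute_force(self):
        # pooling (V, C) with C-1 weights must equal pooling the raw
        # filtered differences (each entry normalized by its expected
        # variance) to within 1e-9 relative
        rng = np.random.default_rng(10)
        for rep in range(5):
            ds, _ = simulate_planted(
                SimulationSpec(n=50, p=20, missing_rate=0.15, seed=200 + rep)
            )
            ds = center_traces(ds)
            field = build_field(ds)
            jj = rng.integers(0, 20, size=8)
            kk = rng.integers(0, 20, size=8)
            keep = jj != kk
            jj, kk = jj[keep], kk[keep]
            for a, axis in enumerate("xyz"):
                pooled, df = field.pooled_variance(a, jj, kk)
                mask = outlier_mask(ds, axis, field.E_raw[a])
                num = den = 0.0
                for j, k in zip(jj, kk):
                    d = ds.coords[:, j, a] - ds.coords[:, k, a]
                    surv = d[mask[:, j, k] & np.isfinite(d)]
                    if surv.size < 2:
                        continue
                    s2 = surv.var(ddof=1) / field.E_filt[a](field.bins.genomic_distance(j, k))
                    num += (surv.size - 1) * s2
                    den += surv.size - 1
                if den == 0:
                    assert np.isnan(pooled)
                    continue
                assert df == pytest.approx(den)
                assert pooled == pytest.approx(num / den, rel=1e-9)

    def test_gaussian_consistency_value(self):
        assert GAUSSIAN_CONSISTENCY == pytest.approx(2.1981, abs=1e-4)
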