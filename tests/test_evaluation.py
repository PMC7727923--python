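"""Resampling, filtering, correlation, summaries and the signed-rank test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import IJF_CORRELATIONS, MCVC_CORRELATIONS
from ctvent.evaluation import (
    median_filter_slicewise,
    resample_with_affine,
    spearman_masked,
    summarize,
    sweep_summary,
    sweep_tau,
    wilcoxon_signed_rank,
    CorrelationRecord,
)
from ctvent.grid import Grid, ImageVolume


def _vol(data, spacing=(1.0, 1.0, 1.0), origin=(0, 0, 0)):
    return ImageVolume(np.asarray(data, float),
                       Grid(np.asarray(data).shape, spacing, origin))


class TestResample:
    def test_identity_affine_same_grid_is_lossless(self):
        rng = np.random.default_rng(0)
        vol = _vol(rng.uniform(size=(8, 7, 6)))
        out = resample_with_affine(vol, np.eye(4), vol.grid)
        assert np.allclose(out.data, vol.data)

    def test_one_voxel_translation_of_constant_image(self):
        vol = _vol(np.full((8, 8, 8), 3.5))
        affine = np.eye(4); affine[0, 3] = 1.0
        out = resample_with_affine(vol, affine, vol.grid)
        inside = np.isfinite(out.data)
        assert np.allclose(out.data[inside], 3.5)

    def test_downsampled_ramp_matches_closed_form(self):
        """A linear ramp resampled 2x coarser equals the ramp at coarse centers."""
        grid = Grid((16, 16, 8), (1.0, 1.0, 1.0))
        idx = np.indices(grid.shape)
        ramp = 2.0 * idx[0] + 0.5 * idx[1] - idx[2]
        vol = ImageVolume(ramp.astype(float), grid)
        coarse = Grid((7, 7, 3), (2.0, 2.0, 2.0), (0.5, 0.5, 0.5))
        out = resample_with_affine(vol, np.eye(4), coarse)
        centers = coarse.voxel_centers().reshape(*coarse.shape, 3)
        expected = 2.0 * centers[..., 0] + 0.5 * centers[..., 1] - centers[..., 2]
        assert np.nanmax(np.abs(out.data - expected)) < 1e-6

    def test_singular_affine_rejected(self):
        vol = _vol(np.zeros((4, 4, 4)))
        bad = np.eye(4); bad[0, 0] = 0.0
        with pytest.raises(ValueError, match="singular"):
            resample_with_affine(vol, bad, vol.grid)

    def test_out_of_field_marked_missing(self):
        vol = _vol(np.ones((4, 4, 4)))
        affine = np.eye(4); affine[0, 3] = 100.0
        out = resample_with_affine(vol, affine, vol.grid)
        assert np.isnan(out.data).all()


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        vol = _vol(np.full((6, 6, 4), 2.0))
        assert np.allclose(median_filter_slicewise(vol).data, 2.0)

    def test_single_impulse_removed(self):
        data = np.zeros((7, 7, 3))
        data[3, 3, 1] = 100.0
        out = median_filter_slicewise(_vol(data))
        assert out.data[3, 3, 1] == 0.0

    def test_matches_sliding_window_oracle(self):
        """Exhaustive reduced-window medians on a random slice."""
        rng = np.random.default_rng(1)
        data = rng.uniform(size=(8, 8, 2))
        out = median_filter_slicewise(_vol(data))
        for z in range(2):
            for i in range(8):
                for j in range(8):
                    window = data[max(0, i - 1):i + 2, max(0, j - 1):j + 2, z]
                    assert np.isclose(out.data[i, j, z], np.median(window))


class TestSpearman:
    def _mask(self, shape):
        return ImageVolume(np.ones(shape, bool), Grid(shape, (1, 1, 1)))

    def test_identical_images_correlate_perfectly(self):
        rng = np.random.default_rng(2)
        a = _vol(rng.uniform(size=(5, 5, 4)))
        assert spearman_masked(a, a, self._mask((5, 5, 4))) == pytest.approx(1.0)

    def test_negated_images_anticorrelate(self):
        rng = np.random.default_rng(3)
        a = _vol(rng.uniform(size=(5, 5, 4)))
        b = a.like(-a.data)
        assert spearman_masked(a, b, self._mask((5, 5, 4))) == pytest.approx(-1.0)

    def test_published_paired_rows_match_rank_pearson_oracle(self):
        """Definitional check: rank both vectors, then Pearson."""
        a = _vol(np.array(IJF_CORRELATIONS).reshape(15, 1, 1))
        b = _vol(np.array(MCVC_CORRELATIONS).reshape(15, 1, 1))
        rho = spearman_masked(a, b, self._mask((15, 1, 1)))
        ra = stats.rankdata(IJF_CORRELATIONS)
        rb = stats.rankdata(MCVC_CORRELATIONS)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_reported_missing(self):
        a = _vol(np.ones((4, 4, 2)))
        b = _vol(np.random.default_rng(0).uniform(size=(4, 4, 2)))
        assert np.isnan(spearman_masked(a, b, self._mask((4, 4, 2))))

    def test_too_few_voxels_rejected(self):
        a = _vol(np.ones((4, 4, 2)))
        m = np.zeros((4, 4, 2), bool); m[0, 0, 0] = m[0, 0, 1] = True
        with pytest.raises(ValueError):
            spearman_masked(a, a, ImageVolume(m, a.grid))

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 500))
    def test_invariance_under_increasing_transforms(self, seed):
        rng = np.random.default_rng(seed)
        a = _vol(rng.uniform(size=(6, 6, 3)))
        b = _vol(rng.uniform(size=(6, 6, 3)))
        m = self._mask((6, 6, 3))
        base = spearman_masked(a, b, m)
        assert spearman_masked(a.like(np.exp(a.data)), b, m) == pytest.approx(base)
        assert spearman_masked(a, b.like(3 * b.data - 7), m) == pytest.approx(base)


class TestSummarize:
    def test_published_rows_reproduce_reported_statistics(self):
        mn, _, med, _, mx = summarize(IJF_CORRELATIONS)
        assert (mn, med, mx) == (0.12, 0.82, 0.90)
        mn, _, med, _, mx = summarize(MCVC_CORRELATIONS)
        assert (mn, med, mx) == (-0.06, 0.48, 0.84)

    def test_single_value(self):
        assert summarize([2.5]) == (2.5, 2.5, 2.5, 2.5, 2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_percentiles_are_ordered(self):
        rng = np.random.default_rng(4)
        mn, q25, med, q75, mx = summarize(rng.normal(size=40))
        assert mn <= q25 <= med <= q75 <= mx


class TestWilcoxon:
    def _enumeration_p(self, diffs):
        """Exhaustive 2^n sign-flip oracle for the two-sided exact p."""
        d = np.asarray(diffs, float)
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_minus = ranks[d < 0].sum()
        w_plus = ranks[d > 0].sum()
        w_obs = min(w_minus, w_plus)
        n = len(ranks)
        signs = ((np.arange(2 ** n)[:, None] >> np.arange(n)) & 1).astype(bool)
        W = np.where(signs, ranks, 0.0).sum(axis=1)
        p = 2.0 * np.mean(W <= w_obs + 1e-12)
        return w_minus, min(1.0, p)

    def test_all_positive_differences(self):
        d = np.arange(1.0, 16.0)
        w_minus, p = wilcoxon_signed_rank(d)
        assert w_minus == 0.0
        assert p == pytest.approx(2.0 / 2 ** 15, abs=1e-15)

    def test_symmetric_pairs_give_p_one(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        _, p = wilcoxon_signed_rank(d)
        assert p == pytest.approx(1.0)

    def test_published_pairs_match_enumeration_oracle(self):
        """W_minus is the midrank of the single negative difference; exact p
        agrees with the 2^15 sign-flip enumeration to 1e-12."""
        w_minus, p = wilcoxon_signed_rank(IJF_CORRELATIONS, MCVC_CORRELATIONS)
        w_oracle, p_oracle = self._enumeration_p(
            np.array(IJF_CORRELATIONS) - np.array(MCVC_CORRELATIONS))
        assert w_minus == w_oracle == 11.0
        assert p == pytest.approx(p_oracle, abs=1e-12)

    @settings(deadline=None, max_examples=10)
    @given(st.integers(0, 300))
    def test_random_paired_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(size=9), 1)
        d = d[d != 0]
        if len(d) < 5:
            return
        w, p = wilcoxon_signed_rank(d)
        w_o, p_o = self._enumeration_p(d)
        assert w == w_o
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 3.0, 0.0])


class TestSweep:
    def test_default_grid_yields_thirty_records(self):
        rng = np.random.default_rng(5)
        ref = _vol(rng.uniform(size=(6, 6, 4)))
        mask = ImageVolume(np.ones((6, 6, 4), bool), ref.grid)
        records = sweep_tau(lambda tau: ref.like(ref.data + tau), ref, mask,
                            median_filter=False)
        assert len(records) == 30
        assert np.allclose([r.tau for r in records], np.linspace(0.01, 0.25, 30))
        assert all(np.isfinite(r.rho) for r in records)

    def test_constant_field_degeneracy_reported_missing(self):
        """A constant recovered field has no ranks: rho is missing, not 0."""
        rng = np.random.default_rng(6)
        ref = _vol(rng.uniform(size=(6, 6, 4)))
        mask = ImageVolume(np.ones((6, 6, 4), bool), ref.grid)
        records = sweep_tau(lambda tau: ref.like(np.full(ref.data.shape, 1.331)),
                            ref, mask, tau_values=[0.05, 0.1], median_filter=False)
        assert all(np.isnan(r.rho) for r in records)

    def test_per_tau_failures_recorded_and_sweep_continues(self):
        rng = np.random.default_rng(7)
        ref = _vol(rng.uniform(size=(6, 6, 4)))
        mask = ImageVolume(np.ones((6, 6, 4), bool), ref.grid)

        def ventilate(tau):
            if tau < 0.05:
                raise RuntimeError("no passing subregions")
            return ref.like(ref.data * (1 + tau))

        records = sweep_tau(ventilate, ref, mask,
                            tau_values=[0.02, 0.1], median_filter=False)
        assert records[0].error is not None and np.isnan(records[0].rho)
        assert records[1].error is None and np.isfinite(records[1].rho)

    def test_summary_curves_ordered(self):
        records = []
        rng = np.random.default_rng(8)
        for tau in (0.05, 0.10):
            for case in range(8):
                records.append(CorrelationRecord(f"c{case}", "IJF", tau,
                                                 rng.uniform(-1, 1), 100))
        s = sweep_summary(records)
        assert (s.minimum <= s.q25).all() and (s.q25 <= s.median).all()
        assert (s.median <= s.q75).all() and (s.q75 <= s.maximum).all()
        assert s.optimal_tau in (0.05, 0.10)
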