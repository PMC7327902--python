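"""Segmentation, skeleton tracing, saturation, correlation, length fits."""

import numpy as np
import pytest

from thinfil import imaging, synth


def _bar_mask(shape=(64, 96), row=30, width=3, col0=20, col1=70):
    m = np.zeros(shape, dtype=bool)
    m[row:row + width, col0:col1] = True
    return m


class TestBinarize:
    def test_all_zero_image_gives_empty_mask(self):
        assert not imaging.binarize_channel(np.zeros((32, 32))).any()

    def test_constant_image_gives_empty_mask(self):
        assert not imaging.binarize_channel(np.full((32, 32), 7.0)).any()

    def test_nan_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            imaging.binarize_channel(img)

    @pytest.mark.parametrize("method", ["mad", "quantile"])
    def test_scale_invariance(self, method, default_scene):
        img, _ = default_scene
        params = imaging.BinarizeParams(method=method)
        m1 = imaging.binarize_channel(img.actin, params)
        m2 = imaging.binarize_channel(img.actin * 2.0, params)
        assert (m1 == m2).all()

    def test_noise_free_filament_mask_covers_truth(self, straight_filament,
                                                   clean_render):
        img = synth.render_scene([straight_filament], clean_render)
        mask = imaging.binarize_channel(img.actin)
        pts = straight_filament.path * clean_render.pixel_scale
        rows = np.rint(pts[:, 1]).astype(int)
        cols = np.rint(pts[:, 0]).astype(int)
        assert mask[rows, cols].mean() > 0.95  # covers the true curve
        # no foreground beyond the PSF-dilated support (4 sigma + morphology)
        halo = int(4 * clean_render.psf_sigma_um * clean_render.pixel_scale) + 3
        far = mask.copy()
        far[rows.min() - halo:rows.max() + halo + 1,
            cols.min() - halo:cols.max() + halo + 1] = False
        assert not far.any()


class TestDecoratedMask:
    def test_idempotent_on_identical_masks(self):
        m = _bar_mask()
        assert (imaging.make_decorated_mask(m, m, dilation_px=0) == m).all()

    def test_disjoint_masks_strict_and_empty(self):
        a = _bar_mask(row=10)
        b = _bar_mask(row=40)
        assert not imaging.make_decorated_mask(a, b, dilation_px=0).any()

    def test_all_true_is_identity_element(self):
        b = _bar_mask()
        full = np.ones_like(b)
        assert (imaging.make_decorated_mask(full, b, dilation_px=0) == b).all()

    def test_dilation_bridges_small_misregistration(self):
        a = _bar_mask(col0=20, col1=40)
        b = np.roll(a, 1, axis=0)
        assert imaging.make_decorated_mask(a, b, dilation_px=1).sum() > 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            imaging.make_decorated_mask(np.zeros((4, 4), bool), np.zeros((5, 4), bool))


class TestSkeletonize:
    def test_straight_bar_gives_one_ordered_trace(self):
        traces = imaging.skeletonize_and_trace(_bar_mask(), pixel_scale=15.0)
        assert len(traces) == 1
        tr = traces[0]
        assert abs(tr.length_px - 50) <= 4  # skeletonization erodes bar ends
        rows = tr.coords[:, 0]
        # essentially collinear (skeleton endpoints may sit one row off)
        assert (rows == np.median(rows)).mean() > 0.9
        cols = tr.coords[:, 1]
        assert np.all(np.diff(cols) == 1) or np.all(np.diff(cols) == -1)  # ordered

    def test_empty_mask(self):
        assert imaging.skeletonize_and_trace(np.zeros((16, 16), bool), 15.0) == []

    def test_two_separated_bars_give_two_traces(self):
        m = _bar_mask(row=10) | _bar_mask(row=45)
        traces = imaging.skeletonize_and_trace(m, 15.0)
        assert len(traces) == 2

    def test_short_components_discarded(self):
        m = np.zeros((32, 32), bool)
        m[5:8, 5:10] = True  # 5 px long
        assert imaging.skeletonize_and_trace(m, 15.0, min_length_px=10) == []

    def test_crossing_filaments_split_at_branch(self):
        m = np.zeros((41, 41), bool)
        m[19:22, :] = True
        m[:, 19:22] = True
        traces = imaging.skeletonize_and_trace(m, 15.0, min_length_px=8)
        assert len(traces) >= 2
        for tr in traces:  # simple paths only: every pixel has <= 2 neighbors
            steps = np.abs(np.diff(tr.coords, axis=0)).max(axis=1)
            assert (steps == 1).all()


class TestSaturation:
    def _trace(self, pixels):
        coords = np.asarray(pixels)
        return imaging.SkeletonTrace(filament_id=0, coords=coords,
                                     length_px=float(len(coords)),
                                     length_um=len(coords) / 15.0)

    def test_full_mask_gives_one(self):
        tr = self._trace([(1, c) for c in range(20)])
        sat = imaging.compute_saturation([tr], np.ones((4, 24), bool))
        assert sat.theta == 1.0

    def test_empty_mask_gives_zero(self):
        tr = self._trace([(1, c) for c in range(20)])
        assert imaging.compute_saturation([tr], np.zeros((4, 24), bool)).theta == 0.0

    def test_pooled_ratio(self):
        # 120 pooled pixels over two traces, 30 decorated -> 0.25
        t1 = self._trace([(1, c) for c in range(80)])
        t2 = self._trace([(3, c) for c in range(40)])
        mask = np.zeros((6, 100), bool)
        mask[1, :10] = True   # 10 decorated on trace 1
        mask[3, :20] = True   # 20 decorated on trace 2
        sat = imaging.compute_saturation([t1, t2], mask)
        assert sat.theta == pytest.approx(0.25)
        assert sat.n_decorated_px == 30 and sat.n_actin_px == 120

    def test_no_traces_errors(self):
        with pytest.raises(ValueError, match="no traces"):
            imaging.compute_saturation([], np.zeros((4, 4), bool))

    def test_scale_invariance_of_theta(self, default_scene):
        img, _ = default_scene
        _, s1 = imaging.analyze_image(img)
        scaled = imaging.TripleChannelImage(img.tpm * 3, img.tn * 3, img.actin * 3,
                                            img.pixel_scale)
        _, s2 = imaging.analyze_image(scaled)
        assert s1["theta"] == pytest.approx(s2["theta"])


class TestProfiles:
    def _image_and_trace(self):
        rng = np.random.default_rng(0)
        img = imaging.TripleChannelImage(
            tpm=rng.random((16, 16)), tn=rng.random((16, 16)),
            actin=rng.random((16, 16)), pixel_scale=15.0)
        coords = np.column_stack([np.full(10, 5), np.arange(3, 13)])
        tr = imaging.SkeletonTrace(0, coords, 10.0, 10 / 15.0)
        return img, tr

    def test_exact_lookup_and_length(self):
        img, tr = self._image_and_trace()
        prof = imaging.extract_profiles(img, [tr])[0]
        assert len(prof) == len(tr.coords)
        np.testing.assert_array_equal(prof.i_tn, img.tn[5, 3:13])
        np.testing.assert_array_equal(prof.i_actin, img.actin[5, 3:13])

    def test_constant_channel_zero_sd(self):
        img, tr = self._image_and_trace()
        img.tn[:] = 4.2
        prof = imaging.extract_profiles(img, [tr])[0]
        assert prof.sd_tn == pytest.approx(0.0, abs=1e-12)
        assert (prof.i_tn == 4.2).all()

    def test_out_of_bounds_names_filament(self):
        img, tr = self._image_and_trace()
        tr.coords[-1] = (5, 99)
        tr.filament_id = 17
        with pytest.raises(ValueError, match="17"):
            imaging.extract_profiles(img, [tr])


class TestCrossCorrelation:
    def _profile(self, x, y):
        return imaging.IntensityProfile(0, i_tn=np.asarray(x, float),
                                        i_tpm=np.zeros(len(x)),
                                        i_actin=np.asarray(y, float))

    def test_self_correlation_is_one(self):
        x = np.sin(np.linspace(0, 6, 50))
        assert imaging.cross_correlation_zero_lag(self._profile(x, x)) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        x = np.sin(np.linspace(0, 6, 50))
        r = imaging.cross_correlation_zero_lag(self._profile(x, -x + 3.0))
        assert r == pytest.approx(-1.0)

    def test_white_noise_near_zero_vs_permutation_null(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        r = imaging.cross_correlation_zero_lag(self._profile(x, y))
        assert abs(r) < 0.05
        null = [np.corrcoef(rng.permutation(x), y)[0, 1] for _ in range(200)]
        assert abs(r) < np.quantile(np.abs(null), 0.995) + 0.02

    def test_bounds(self, analyzed_scene):
        *_, table, _ = analyzed_scene
        r = table[["r_tn_actin", "r_tpm_actin"]].values
        r = r[np.isfinite(r)]
        assert ((-1 - 1e-12 <= r) & (r <= 1 + 1e-12)).all()

    def test_zero_variance_flagged_and_excluded(self):
        flat = self._profile(np.ones(10), np.arange(10))
        with pytest.raises(imaging.ZeroVarianceError):
            imaging.cross_correlation_zero_lag(flat)
        good = self._profile(np.arange(10), np.arange(10))
        mean, excluded = imaging.mean_image_correlation([flat, good])
        assert excluded == 1 and mean == pytest.approx(1.0)

    def test_too_short_profile(self):
        with pytest.raises(ValueError, match=">= 3"):
            imaging.cross_correlation_zero_lag(self._profile([1, 2], [1, 2]))


class TestLengths:
    def _trace_with_flags(self, flags):
        coords = np.column_stack([np.full(len(flags), 2), np.arange(len(flags))])
        tr = imaging.SkeletonTrace(0, coords, float(len(flags)),
                                   len(flags) / 15.0,
                                   decorated_flags=np.asarray(flags, bool))
        return tr

    def test_fully_decorated_one_run_equal_to_length(self):
        tr = self._trace_with_flags([1] * 30)
        fil, runs = imaging.measure_lengths([tr], pixel_scale=15.0)
        assert len(runs) == 1
        assert runs[0] == pytest.approx(tr.length_um)

    def test_alternating_flags_unit_runs(self):
        tr = self._trace_with_flags([1, 0] * 15)
        _, runs = imaging.measure_lengths([tr], pixel_scale=15.0)
        assert len(runs) == 15
        assert np.allclose(runs, 1 / 15.0)  # single-pixel runs

    def test_run_total_never_exceeds_filament(self, analyzed_scene):
        *_, table, _ = analyzed_scene
        assert (table["decorated_um"] <= table["length_um"] + 1e-9).all()


class TestExponentialFit:
    def test_recovers_forty_sites(self):
        mean_um = 40 * synth.SITE_LENGTH_UM
        x = synth.sample_filament_lengths(500, mean_um, 0.0, seed=8)
        fit = imaging.fit_exponential(x)
        assert abs(fit.mean - mean_um) < 3 * fit.se

    def test_degenerate_sample_flagged(self):
        fit = imaging.fit_exponential(np.full(20, 1.5))
        assert fit.degenerate

    def test_truncation_aware_beats_naive_mean(self):
        # observing an exponential only above `lo` biases the naive mean by +lo;
        # the truncation-aware MLE recovers the underlying scale
        lo, scale = 1.0, 2.0
        x = synth.sample_filament_lengths(4000, lo + scale, lo, seed=9)
        naive = x.mean()
        fit = imaging.fit_exponential(x, truncation=lo)
        assert abs(fit.mean - scale) < abs(naive - scale)
        assert abs(fit.mean - scale) < 3 * fit.se

    @pytest.mark.parametrize("bad", [np.array([1.0] * 5), -np.ones(20)])
    def test_input_errors(self, bad):
        with pytest.raises(ValueError):
            imaging.fit_exponential(bad)
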