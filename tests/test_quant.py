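"""Spot measurement, TFI aggregation, and the per-frame pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evquant import (
    ImageSimConfig,
    QuantConfig,
    Spot,
    TIRFImage,
    aggregate_sample,
    apply_histogram_cutoff,
    build_histogram,
    colocalization_fraction,
    compute_tfi,
    denoise_image,
    detect_spots,
    filter_spots_by_size,
    measure_spot,
    measure_spots,
    quantify_image,
    simulate_tirf_image,
)


def _spot_with_net(net: float, diameter: float = 10.0) -> Spot:
    return Spot(
        pixel_mask=np.array([[0, 0]]),
        centroid=(0.0, 0.0),
        equivalent_diameter_px=diameter,
        net_intensity=net,
    )


def _block_image(size=21, bg=2.0, block_value=10.0, block_at=(9, 9), block_shape=(2, 2)):
    px = np.full((size, size), bg)
    r, c = block_at
    h, w = block_shape
    px[r : r + h, c : c + w] = block_value
    mask = np.argwhere(px == block_value)
    return TIRFImage(pixels=px), mask


class TestMeasureSpot:
    def test_hand_example_net_intensity(self):
        # 4-pixel mask at 10 on constant background 2: net = (10-2)*4 = 32;
        # aperture padding adds only background-level pixels, which cancel
        img, mask = _block_image()
        spot = Spot(pixel_mask=mask, centroid=(9.5, 9.5), equivalent_diameter_px=2.26)
        for pad in (0, 3):
            m = measure_spot(img, spot, QuantConfig(aperture_pad_px=pad))
            assert m.net_intensity == pytest.approx(32.0, abs=1e-9)
            assert m.local_background_mean == pytest.approx(2.0)

    def test_spot_at_background_level_nets_zero(self):
        img, mask = _block_image(block_value=2.0)
        mask = np.array([[9, 9], [9, 10], [10, 9], [10, 10]])
        spot = Spot(pixel_mask=mask, centroid=(9.5, 9.5), equivalent_diameter_px=2.26)
        m = measure_spot(img, spot, QuantConfig())
        assert m.net_intensity == pytest.approx(0.0, abs=1e-9)

    def test_offset_invariance_exact(self):
        img, mask = _block_image()
        spot = Spot(pixel_mask=mask, centroid=(9.5, 9.5), equivalent_diameter_px=2.26)
        cfg = QuantConfig()
        base = measure_spot(img, spot, cfg).net_intensity
        shifted = TIRFImage(pixels=img.pixels + 57.3)
        assert measure_spot(shifted, spot, cfg).net_intensity == pytest.approx(
            base, abs=1e-9
        )

    def test_net_intensity_matches_interior_sum_identity(self):
        rng = np.random.default_rng(0)
        img = TIRFImage(pixels=rng.uniform(0, 50, (31, 31)))
        mask = np.argwhere(np.zeros((31, 31)) == 0)[200:212]
        spot = Spot(pixel_mask=mask, centroid=(6.0, 15.0), equivalent_diameter_px=3.9)
        m = measure_spot(img, spot, QuantConfig())
        expected = m.interior_intensities.sum() - len(
            m.interior_intensities
        ) * m.local_background_mean
        assert m.net_intensity == pytest.approx(expected, rel=1e-12)

    def test_background_undeterminable_dropped(self):
        px = np.full((9, 9), 5.0)
        mask = np.argwhere(px >= 0)  # mask covers the whole frame
        spot = Spot(pixel_mask=mask, centroid=(4, 4), equivalent_diameter_px=10.0)
        assert measure_spot(TIRFImage(pixels=px), spot, QuantConfig()) is None


class TestSizeFilter:
    def test_inclusive_bounds(self):
        diam = [5, 6, 13, 20, 21]
        spots = [_spot_with_net(0.0, d) for d in diam]
        kept = filter_spots_by_size(spots, 6, 20)
        assert sorted(s.equivalent_diameter_px for s in kept) == [6, 13, 20]
        dropped = [s for s in spots if s.equivalent_diameter_px in (5, 21)]
        assert all(s.tag == "aggregate-or-noise" for s in dropped)

    def test_empty_and_identity(self):
        assert filter_spots_by_size([], 6, 20) == []
        spots = [_spot_with_net(0.0, d) for d in (7, 10, 19)]
        assert filter_spots_by_size(spots, 6, 20) == spots

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_spots_by_size([], 21, 20)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        diams=st.lists(st.floats(1, 40), min_size=0, max_size=30),
        lo=st.floats(2, 10),
        width=st.floats(1, 20),
    )
    def test_widening_window_never_loses_spots(self, diams, lo, width):
        spots = [_spot_with_net(0.0, d) for d in diams]
        narrow = filter_spots_by_size(list(spots), lo + 1, lo + width)
        wide = filter_spots_by_size(list(spots), lo, lo + width + 2)
        assert len(wide) >= len(narrow)


class TestHistogramAndCutoff:
    def test_bin_conventions(self):
        spots = [_spot_with_net(v) for v in (1.0, 2.0, 3.0)]
        h = build_histogram(spots, np.array([0.0, 1.5, 3.5]))
        assert list(h.counts) == [1, 2]
        single = build_histogram([_spot_with_net(float(i)) for i in range(10)], 1)
        assert list(single.counts) == [10]
        empty = build_histogram([], 5)
        assert empty.counts.sum() == 0
        with pytest.raises(ValueError):
            build_histogram(spots, 0)

    def test_cutoff_strictness(self):
        spots = [_spot_with_net(v) for v in (5.0, 10.0, 20.0)]
        kept = apply_histogram_cutoff(spots, 10.0)
        assert [s.net_intensity for s in kept] == [20.0]
        assert apply_histogram_cutoff(spots, -1e12) == spots
        assert apply_histogram_cutoff(spots, 21.0) == []
        with pytest.raises(ValueError):
            apply_histogram_cutoff(spots, float("nan"))

    def test_raising_cutoff_never_raises_tfi(self, rng):
        # monotone for non-negative cutoffs: every spot removed by a raise
        # carries positive net intensity
        nets = rng.normal(50, 40, size=60)
        spots = [[_spot_with_net(float(v)) for v in nets]]
        tfis = []
        for cutoff in np.linspace(0, 150, 15):
            retained = [apply_histogram_cutoff(spots[0], float(cutoff))]
            tfis.append(compute_tfi(retained, l=1).tfi)
        assert all(a >= b - 1e-9 for a, b in zip(tfis, tfis[1:]))


class TestComputeTFI:
    def test_hand_examples(self):
        one = [[_spot_with_net(32.0)]]
        assert compute_tfi(one, l=1).tfi == pytest.approx(32.0)
        two = [[_spot_with_net(32.0)], [_spot_with_net(32.0)]]
        assert compute_tfi(two).tfi == pytest.approx(32.0)
        empty = [[] for _ in range(100)]
        assert compute_tfi(empty).tfi == 0.0
        with pytest.raises(ValueError):
            compute_tfi([], l=0)

    def test_matches_per_pixel_double_loop(self, rng):
        # brute-force oracle: explicit sum over images, spots, pixels
        for _ in range(10):
            n_images = int(rng.integers(1, 5))
            images_spots = []
            brute = 0.0
            for _k in range(n_images):
                frame = []
                for _j in range(int(rng.integers(0, 6))):
                    n_px = int(rng.integers(1, 30))
                    vals = rng.uniform(0, 100, n_px)
                    bg = float(rng.uniform(0, 20))
                    for v in vals:
                        brute += v - bg
                    frame.append(
                        Spot(
                            pixel_mask=np.zeros((n_px, 2), dtype=int),
                            centroid=(0, 0),
                            equivalent_diameter_px=2 * np.sqrt(n_px / np.pi),
                            interior_intensities=vals,
                            local_background_mean=bg,
                            net_intensity=float(vals.sum() - n_px * bg),
                        )
                    )
                images_spots.append(frame)
            result = compute_tfi(images_spots)
            assert result.tfi == pytest.approx(brute / n_images, rel=1e-9, abs=1e-9)


class TestAggregateSample:
    def test_mean_of_wells(self):
        from evquant import WellResult

        wells = [
            WellResult("w1", "mrna", 100, [], 30000.0),
            WellResult("w2", "mrna", 100, [], 34000.0),
        ]
        assert aggregate_sample(wells)["mrna"] == pytest.approx(32000.0)
        assert aggregate_sample(wells[:1])["mrna"] == pytest.approx(30000.0)
        zero = [
            WellResult("w1", "mprotein", 100, [], 0.0),
            WellResult("w2", "mprotein", 100, [], 0.0),
        ]
        assert aggregate_sample(zero)["mprotein"] == 0.0
        with pytest.raises(ValueError):
            aggregate_sample([])


class TestColocalization:
    def test_fractions(self):
        base = np.zeros((20, 20), dtype=bool)
        ch1 = base.copy()
        ch1[:10, :10] = True  # 100 px
        ch2 = base.copy()
        ch2[:10, :5] = True  # overlap 50
        r = colocalization_fraction(ch1, ch2)
        assert (r.coloc_area_px, r.ch1_area_px, r.fraction) == (50, 100, 0.5)
        assert colocalization_fraction(ch2, ch1).fraction == 1.0  # ch1 subset
        ch3 = base.copy()
        ch3[15:, 15:] = True
        assert colocalization_fraction(ch1, ch3).fraction == 0.0
        with pytest.raises(ValueError):
            colocalization_fraction(base, ch1)


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = TIRFImage(pixels=np.full((64, 64), 37.0))
        out = denoise_image(img, QuantConfig())
        assert np.allclose(out.pixels, 37.0, rtol=1e-6)

    def test_isolated_spikes_suppressed(self, rng):
        px = np.full((64, 64), 100.0)
        noise_sd = 3.0
        px += rng.normal(0, noise_sd, px.shape)
        locs = [(10, 10), (30, 45), (50, 20)]
        for r, c in locs:
            px[r, c] += 10 * noise_sd
        # aggressive smoothing configuration for spike removal
        cfg = QuantConfig(wavelet_k=5.0)
        out = denoise_image(TIRFImage(pixels=np.clip(px, 0, None)), cfg)
        for r, c in locs:
            residual = out.pixels[r, c] - np.median(out.pixels)
            assert residual <= 0.2 * 10 * noise_sd

    def test_spot_peak_position_stable(self):
        cfg = ImageSimConfig(
            seed=21,
            image_size_px=(128, 128),
            spot_count=1,
            psf_sigma_px=2.0,
            n_speck=0,
            n_aggregate=0,
            amplitude_distribution=("constant", {"value": 26000.0}),  # SNR ~ 10
        )
        img, truth = simulate_tirf_image(cfg)
        pre = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        out = denoise_image(img, QuantConfig())
        post = np.unravel_index(np.argmax(out.pixels), out.pixels.shape)
        assert np.hypot(pre[0] - post[0], pre[1] - post[1]) <= 1.0

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            denoise_image(TIRFImage(pixels=np.ones((4, 4))), QuantConfig())


class TestDetect:
    def test_blank_noiseless_image(self):
        img = TIRFImage(pixels=np.full((64, 64), 10.0))
        assert detect_spots(img, QuantConfig()) == []

    def test_single_spot_detected_with_accurate_centroid(self):
        cfg = ImageSimConfig(
            seed=3,
            image_size_px=(128, 128),
            spot_count=1,
            n_speck=0,
            n_aggregate=0,
            amplitude_distribution=("constant", {"value": 14000.0}),
        )
        img, truth = simulate_tirf_image(cfg)
        spots = quantify_image(img, QuantConfig())
        assert len(spots) == 1
        err = np.hypot(
            spots[0].centroid[0] - truth[0].row, spots[0].centroid[1] - truth[0].col
        )
        assert err <= 1.0

    def test_two_well_separated_spots(self):
        px = np.full((128, 128), 100.0)
        img0 = TIRFImage(pixels=px)
        from evquant.simulate import _render_spot

        work = img0.pixels.copy()
        _render_spot(work, 40.0, 40.0, 14000.0, 3.0)
        _render_spot(work, 90.0, 90.0, 14000.0, 3.0)
        rng = np.random.default_rng(0)
        noisy = rng.poisson(work).astype(float)
        spots = quantify_image(TIRFImage(pixels=noisy), QuantConfig())
        assert len(spots) == 2

    def test_disjoint_masks(self, recovery_sim_cfg):
        img, _ = __import__("evquant").simulate_tirf_image(recovery_sim_cfg(0))
        cands = detect_spots(img, QuantConfig(denoise=False))
        seen = set()
        for s in cands:
            for r, c in s.pixel_mask:
                assert (r, c) not in seen
                seen.add((r, c))
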