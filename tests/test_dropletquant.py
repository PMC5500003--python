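"""Droplet segmentation, shape filters and percent coverage."""

import numpy as np
import pytest

from taurna import synthdata
from taurna.dropletquant import (
    BrightFieldImage,
    SegmentationParams,
    aggregate,
    apply_filters,
    buffer_threshold,
    coverage_percent,
    quantify,
    segment_and_measure,
)


def make_image(pixels, pixel_size_um=0.25, **kwargs):
    return BrightFieldImage(
        pixels=np.asarray(pixels), pixel_size_um=pixel_size_um, **kwargs
    )


class TestBufferThreshold:
    def test_uniform_image(self):
        image = make_image(np.full((32, 32), 100, dtype=np.uint16))
        assert buffer_threshold(image) == 100.0

    def test_noisy_buffer_mean_concentrates(self):
        rng = np.random.default_rng(0)
        pixels = np.clip(
            np.rint(rng.normal(2000, 50, size=(200, 200))), 0, 4095
        ).astype(np.uint16)
        image = make_image(pixels)
        assert abs(buffer_threshold(image) - 2000) < 3 * 50 / 200  # 3 sd / sqrt(N)

    def test_saturated_buffer_warns(self):
        image = make_image(np.full((32, 32), 4095, dtype=np.uint16))
        with pytest.warns(UserWarning, match="saturated"):
            assert buffer_threshold(image) == 4095.0


class TestSegmentation:
    def test_disk_pixel_count_matches_rasterization_oracle(self):
        image, truth = synthdata.gen_droplet_image(
            ellipses=[((250, 250), (50, 50), 0.0)], seed=1
        )
        regions = segment_and_measure(image, SegmentationParams(threshold=1700))
        assert len(regions) == 1
        # brute-force count of pixels satisfying the disk inequality
        rr, cc = np.mgrid[0:500, 0:500]
        oracle = int((((rr - 250) / 50) ** 2 + ((cc - 250) / 50) ** 2 <= 1).sum())
        assert regions[0].pixel_count == oracle
        assert regions[0].eccentricity < 0.1
        assert regions[0].equivalent_diameter_um == pytest.approx(
            2 * np.sqrt(oracle * 0.25 ** 2 / np.pi), rel=1e-12
        )

    def test_elongated_ellipse_eccentricity(self):
        image, _ = synthdata.gen_droplet_image(
            ellipses=[((250, 250), (40, 8), 0.0)], seed=1
        )
        regions = segment_and_measure(image, SegmentationParams(threshold=1700))
        assert len(regions) == 1
        assert regions[0].eccentricity == pytest.approx(
            np.sqrt(1 - (8 / 40) ** 2), abs=0.01
        )

    def test_blank_image_gives_no_regions(self):
        image, _ = synthdata.gen_droplet_image(seed=1)
        assert segment_and_measure(image, SegmentationParams(threshold=1700)) == []

    def test_border_touching_flagged(self):
        image, _ = synthdata.gen_droplet_image(
            ellipses=[((0, 250), (30, 30), 0.0)], seed=1
        )
        regions = segment_and_measure(image, SegmentationParams(threshold=1700))
        assert regions[0].touches_border


class TestFilters:
    def _region(self, eccentricity, diameter_um):
        from taurna.dropletquant import DropletRegion

        return DropletRegion(
            pixel_count=100, area_um2=6.25, eccentricity=eccentricity,
            equivalent_diameter_um=diameter_um, centroid=(0, 0),
            touches_border=False,
        )

    def test_filter_rules(self):
        params = SegmentationParams(threshold=0)
        keepers = [self._region(0.0, 10.0), self._region(0.9, 1.0)]
        rejects = [self._region(0.98, 10.0), self._region(0.0, 0.8)]
        kept, filtered = apply_filters(keepers + rejects, params)
        assert kept == keepers
        assert filtered == rejects

    def test_partition_exhaustive(self):
        params = SegmentationParams(threshold=0)
        regions = [self._region(e, d) for e in (0.0, 0.95) for d in (0.5, 5.0)]
        kept, filtered = apply_filters(regions, params)
        assert len(kept) + len(filtered) == len(regions)

    def test_tightening_filters_never_raises_coverage(self):
        image, _ = synthdata.gen_droplet_image(
            ellipses=[
                ((100, 100), (40, 40), 0.0),
                ((300, 300), (30, 8), 0.3),
                ((420, 100), (2, 2), 0.0),
            ],
            seed=3,
        )
        def coverage(max_ecc, min_diam):
            return quantify(
                image,
                SegmentationParams(
                    threshold=1700, max_eccentricity=max_ecc,
                    min_diameter_um=min_diam,
                ),
            ).percent_coverage

        baseline = coverage(0.9, 1.0)
        assert coverage(0.5, 1.0) <= baseline
        assert coverage(0.9, 5.0) <= baseline


class TestCoverage:
    def test_end_to_end_noise_free_equals_truth_exactly(self):
        ellipses = [
            ((120, 120), (40, 40), 0.0),
            ((350, 300), (50, 30), 0.7),
            ((420, 100), (20, 16), 0.0),
        ]
        image, truth = synthdata.gen_droplet_image(ellipses=ellipses, seed=4)
        result = quantify(image, SegmentationParams(threshold=1700))
        assert result.percent_coverage == truth["coverage_pct"]

    def test_single_disk_coverage_formula(self):
        image, truth = synthdata.gen_droplet_image(
            ellipses=[((250, 250), (50, 50), 0.0)], seed=1
        )
        result = quantify(image, SegmentationParams(threshold=1700))
        n_px = truth["objects"][0]["pixel_count"]
        assert result.percent_coverage == pytest.approx(
            100 * n_px / 250000, abs=1e-12
        )

    def test_full_mask_and_blank(self):
        blank, _ = synthdata.gen_droplet_image(seed=1)
        assert quantify(blank, SegmentationParams(threshold=1700)).percent_coverage == 0.0
        dark = make_image(np.zeros((64, 64), dtype=np.uint16))
        assert quantify(dark, SegmentationParams(threshold=100)).percent_coverage == 100.0

    def test_removing_a_region_decreases_coverage(self):
        image, _ = synthdata.gen_droplet_image(
            ellipses=[((100, 100), (30, 30), 0.0), ((300, 300), (30, 30), 0.0)],
            seed=5,
        )
        params = SegmentationParams(threshold=1700)
        regions = segment_and_measure(image, params)
        kept, _ = apply_filters(regions, params)
        full = coverage_percent(kept, image, params).percent_coverage
        partial = coverage_percent(kept[:-1], image, params).percent_coverage
        assert partial < full

    def test_intensity_affine_invariance(self):
        image, _ = synthdata.gen_droplet_image(
            ellipses=[((100, 100), (30, 30), 0.0)], background_sd=30.0, seed=6
        )
        base = quantify(image, SegmentationParams(threshold=1850))
        mapped = BrightFieldImage(
            pixels=image.pixels.astype(np.int64) * 3 + 7,
            pixel_size_um=image.pixel_size_um, bit_depth=16,
        )
        result = quantify(mapped, SegmentationParams(threshold=1850 * 3 + 7))
        assert result.percent_coverage == base.percent_coverage
        assert result.kept_count == base.kept_count

    def test_aggregate_by_condition(self):
        results = []
        for rep in range(3):
            image, _ = synthdata.gen_droplet_image(
                ellipses=[((100 + 20 * rep, 100), (30, 30), 0.0)],
                background_sd=20.0, seed=10 + rep, condition="no-salt",
                replicate=rep,
            )
            results.append(quantify(image, SegmentationParams(threshold=1850)))
        table = aggregate(results)
        assert list(table["n"]) == [3]
        assert table.loc[0, "mean"] == pytest.approx(
            np.mean([r.percent_coverage for r in results])
        )

    def test_pixel_size_required(self):
        with pytest.raises(ValueError):
            make_image(np.zeros((32, 32), dtype=np.uint16), pixel_size_um=0.0)
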