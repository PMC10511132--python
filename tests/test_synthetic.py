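"""Generator-level checks: determinism, stated distributions, truth tables."""

import numpy as np
import pandas as pd
import pytest

from exmpipe import synthetic
from exmpipe.types import ImageVolume, PlacementError


class TestCellImages:
    def test_same_seed_bit_identical(self):
        a = synthetic.gen_cell_images(5, 200, seed=7)
        b = synthetic.gen_cell_images(5, 200, seed=7)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].labels, b[1].labels)
        pd.testing.assert_frame_equal(
            a[2].truth_tables["cells"], b[2].truth_tables["cells"]
        )

    def test_circle_truth_axes(self):
        _, _, truth = synthetic.gen_cell_images(
            1, 128, seed=0, radius_range=(20, 20), axis_ratio_range=(1, 1),
            noise_sd=0.0,
        )
        cell = truth.truth_tables["cells"].iloc[0]
        assert cell["major_px"] == cell["minor_px"] == 40

    def test_axis_ratio_mean_within_3_se(self):
        _, _, truth = synthetic.gen_cell_images(
            30, 900, seed=3, axis_ratio_range=(1.0, 2.0)
        )
        ratios = truth.truth_tables["cells"]["axis_ratio"]
        se = np.sqrt(1 / 12) / np.sqrt(30)  # SD of U(1,2) is 1/sqrt(12)
        assert abs(ratios.mean() - 1.5) < 3 * se

    def test_field_too_small_raises(self):
        with pytest.raises(PlacementError):
            synthetic.gen_cell_images(30, 64, seed=0, radius_range=(15, 20))


class TestExpansionPair:
    @pytest.fixture(scope="class")
    def pre(self):
        return synthetic.gen_cell_images(4, 96, seed=5, radius_range=(7, 10))[0]

    def test_zero_distortion_gives_zero_field(self, pre):
        _, field, _ = synthetic.gen_expansion_pair(pre, 4.2, 0.0, seed=1)
        assert field.rms() == 0.0

    def test_field_rms_matches_request(self, pre):
        _, field, _ = synthetic.gen_expansion_pair(pre, 4.2, 0.5, 5.0, seed=2)
        assert abs(field.rms() - 0.5) / 0.5 < 0.10

    def test_long_axis_scales_by_factor(self, pre):
        from exmpipe import qc
        from exmpipe.types import SegmentationMap

        post, _, _ = synthetic.gen_expansion_pair(pre, 4.2, 0.0, seed=3)
        # measure the same structure pre and post via thresholded masks
        pre_mask = (pre.data > 0.5 * pre.data.max()).astype(np.int32)
        post_mask = (post.data > 0.5 * post.data.max()).astype(np.int32)
        import skimage.measure as m

        pre_len = max(
            r.axis_major_length for r in m.regionprops(m.label(pre_mask))
        )
        post_len = max(
            r.axis_major_length for r in m.regionprops(m.label(post_mask))
        )
        assert post_len / pre_len == pytest.approx(4.2, rel=0.03)

    def test_invalid_parameters_rejected(self, pre):
        with pytest.raises(ValueError):
            synthetic.gen_expansion_pair(pre, 0.9)
        with pytest.raises(ValueError):
            synthetic.gen_expansion_pair(pre, 4.2, 0.5, smoothness=0.0)

    def test_determinism(self, pre):
        a = synthetic.gen_expansion_pair(pre, 3.0, 0.3, seed=9)
        b = synthetic.gen_expansion_pair(pre, 3.0, 0.3, seed=9)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(
            a[1].displacement, b[1].displacement
        )


class TestFishSpots:
    def test_poisson_mean_within_3_se(self):
        _, seg, _ = synthetic.gen_cell_images(
            60, 2000, seed=11, radius_range=(42, 48),
            axis_ratio_range=(1.0, 1.3),
        )
        _, truth = synthetic.gen_fish_spots(
            seg, 200.0, psf_sigma=1.0, seed=12
        )
        spots_truth = truth.truth_tables["spots"]
        counts = (
            spots_truth.groupby("cell_id").size()
            .reindex(seg.label_ids, fill_value=0)
        )
        se = np.sqrt(200 / 60)
        assert abs(counts.mean() - 200) < 3 * se

    def test_tiny_rate_mostly_empty(self, cell_field):
        _, seg, _ = cell_field
        _, truth = synthetic.gen_fish_spots(seg, 1e-4, seed=13)
        assert len(truth.truth_tables["spots"]) <= 1

    def test_zero_noise_blob_count_matches_truth(self, cell_field):
        from exmpipe import spots

        _, seg, _ = cell_field
        img, truth = synthetic.gen_fish_spots(seg, 10.0, noise_sd=0.0, seed=14)
        detected = spots.detect_spots(img, 1.5, 5.0)
        assert len(detected) == len(truth.truth_tables["spots"])

    def test_rejects_nonpositive_rate(self, cell_field):
        with pytest.raises(ValueError):
            synthetic.gen_fish_spots(cell_field[1], 0.0)


class TestAxonProfile:
    def test_noiseless_maxima_spacing(self):
        profile, _ = synthetic.gen_axon_profile(
            190.0, 10, noise_sd=0.0, expansion_factor=1.0, sampling_nm=10.0
        )
        from scipy.signal import find_peaks

        idx, _ = find_peaks(profile.intensities)
        spacings = np.diff(profile.positions[idx])
        assert np.allclose(spacings, 190.0, atol=10.0)

    def test_zero_amplitude_flat(self):
        profile, _ = synthetic.gen_axon_profile(
            amplitude=0.0, noise_sd=0.0, background=0.3
        )
        assert np.allclose(profile.intensities, 0.3)

    def test_jittered_centers_mean_spacing(self):
        spacings = []
        for s in range(20):
            _, truth = synthetic.gen_axon_profile(
                190.0, 20, jitter_sd_nm=10.0, seed=s
            )
            spacings.extend(np.diff(truth.truth_tables["ring_centers_nm"]))
        spacings = np.array(spacings)
        se = spacings.std() / np.sqrt(len(spacings))
        assert abs(spacings.mean() - 190.0) < 3 * se

    def test_coarse_sampling_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_axon_profile(190.0, sampling_nm=60.0)


class TestExseqStacks:
    def test_zero_error_realized_equals_barcode(self, codebook):
        _, _, truth = synthetic.gen_exseq_stacks(
            codebook, n_amplicons=50, seed=21
        )
        reads = truth.truth_tables["reads"]
        assert (reads["realized_bases"] == reads["barcode"]).all()

    def test_error_rate_fraction_with_errors(self, codebook):
        _, _, truth = synthetic.gen_exseq_stacks(
            codebook, n_amplicons=200, base_error_rate=0.05, seed=22
        )
        reads = truth.truth_tables["reads"]
        frac = (reads["realized_bases"] != reads["barcode"]).mean()
        expected = 1 - 0.95**7
        se = np.sqrt(expected * (1 - expected) / len(reads))
        assert abs(frac - expected) < 3 * se

    def test_fiducial_count(self, codebook):
        _, _, truth = synthetic.gen_exseq_stacks(
            codebook, n_amplicons=30, n_fiducials=4, seed=23
        )
        assert len(truth.truth_tables["fiducials"]) == 4

    def test_empty_codebook_rejected(self):
        from exmpipe.exseq import Codebook

        with pytest.raises(ValueError):
            Codebook(barcodes={}, channel_to_base=synthetic.CHANNEL_TO_BASE)


class TestCountMatrix:
    def test_null_enrichment_no_clone_signal(self):
        matrix, truth = synthetic.gen_count_matrix(
            400, marker_enrichment=1.0, seed=31
        )
        from scipy.stats import ttest_ind

        labels = truth.truth_tables["labels"]
        gene = truth.truth_tables["markers_a"][0]
        a = matrix.loc[labels == "clone_a", gene]
        b = matrix.loc[labels == "clone_b", gene]
        _, p = ttest_ind(a, b, equal_var=False)
        assert p > 1e-3

    def test_clone_fraction_binomial(self):
        _, truth = synthetic.gen_count_matrix(2000, clone_fraction=0.5, seed=32)
        n_a = (truth.truth_tables["labels"] == "clone_a").sum()
        assert abs(n_a - 1000) < 3 * np.sqrt(2000 * 0.25)

    def test_extreme_totals_escape_retention_window(self):
        means = np.array([40.0] * 30 + [3500.0] * 30)
        matrix, _ = synthetic.gen_count_matrix(
            60, mean_counts=means, seed=33, total_cv=0.05
        )
        totals = matrix.sum(axis=1)
        assert (totals[:30] < 50).mean() > 0.8
        assert (totals[30:] > 3000).mean() > 0.8

    def test_overlapping_markers_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_count_matrix(
                10, markers_a=["X", "Y"], markers_b=["Y", "Z"]
            )

    def test_determinism(self):
        a, _ = synthetic.gen_count_matrix(100, seed=5)
        b, _ = synthetic.gen_count_matrix(100, seed=5)
        pd.testing.assert_frame_equal(a, b)
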