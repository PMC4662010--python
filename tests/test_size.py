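import numpy as np
import pytest

from conftest import make_segment
from optmap import size as sizing
from optmap.size import (
    SizingParams,
    build_intensity_mask,
    construct_rmap,
    estimate_background,
    estimate_conversion_factor,
    identify_standards,
    integrated_fluorescence,
)
from optmap.types import (
    ConversionFactor,
    FragmentMeasurement,
    Frame,
    MoleculeGroup,
    lambda_bsu36i,
)

IDENTITY = [(0, 0)]


def measurement(fluor, n_px=10, span=2):
    return FragmentMeasurement(fluor, n_px, span)


class TestMask:
    def test_seven_column_interior_fragment_has_35_pixels(self):
        seg = make_segment((20, 5), (20, 11))
        mask = build_intensity_mask(seg, n_rows=100)
        assert mask.shape[0] == 35
        assert set(mask[:, 0]) == set(range(18, 23))

    def test_single_pixel_segment_gets_five_pixel_column(self):
        seg = make_segment((20, 5), (20, 5))
        mask = build_intensity_mask(seg, n_rows=100)
        assert mask.shape[0] == 5

    def test_mask_clipped_at_frame_border(self):
        seg = make_segment((1, 5), (1, 5))
        mask = build_intensity_mask(seg, n_rows=100)
        assert set(mask[:, 0]) == {0, 1, 2, 3}


class TestBackground:
    def test_constant_frame(self):
        frame = Frame(np.full((30, 30), 100.0))
        seg = make_segment((15, 10), (15, 15))
        mask = build_intensity_mask(seg, n_rows=30)
        assert estimate_background(frame, [mask]) == 100.0

    def test_known_additive_background_recovered(self, noisy_channel):
        params, frames, _ = noisy_channel
        frame = frames[0]
        from optmap.skeletonize import SkeletonizationParams, extract_segments

        segs = extract_segments(frame, SkeletonizationParams())
        masks = [build_intensity_mask(s, n_rows=frame.shape[0]) for s in segs]
        bg = estimate_background(frame, masks)
        assert bg == pytest.approx(params.background_adu, abs=2.0)

    def test_fully_masked_frame_rejected(self):
        frame = Frame(np.full((7, 3), 5.0))
        full = np.array([(r, c) for r in range(7) for c in range(3)])
        with pytest.raises(ValueError, match="masked"):
            estimate_background(frame, [full])


class TestIntegration:
    def test_uniform_excess_sums_exactly(self):
        img = np.full((40, 40), 110.0)
        frame = Frame(img)
        seg = make_segment((20, 10), (20, 16))
        mask = build_intensity_mask(seg, n_rows=40)
        total, n = integrated_fluorescence([frame], IDENTITY, mask, [100.0])
        assert (total, n) == (350.0, 35)

    def test_linearity_in_above_background_intensity(self):
        rng = np.random.default_rng(4)
        base = 100.0 + rng.uniform(0, 50, size=(40, 40))
        seg = make_segment((20, 10), (20, 16))
        mask = build_intensity_mask(seg, n_rows=40)
        t1, _ = integrated_fluorescence([Frame(base)], IDENTITY, mask, [100.0])
        doubled = 100.0 + 2 * (base - 100.0)
        t2, _ = integrated_fluorescence([Frame(doubled)], IDENTITY, mask, [100.0])
        assert t2 == pytest.approx(2 * t1)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            integrated_fluorescence(
                [Frame(np.ones((10, 10)))], IDENTITY, np.empty((0, 2)), [0.0]
            )

    def test_overlap_region_counted_once(self):
        # two frames covering the same scene with 50% overlap
        img = np.full((20, 40), 100.0)
        img[10, :] = 200.0
        f0 = Frame(img, frame_index=0)
        f1 = Frame(img.copy(), frame_index=1)
        offsets = [(0, 0), (0, 20)]
        seg = make_segment((10, 5), (10, 54))
        mask = build_intensity_mask(seg, n_rows=20)
        total, n = integrated_fluorescence([f0, f1], offsets, mask, [100.0, 100.0])
        assert n == 250  # 5 rows x 50 cols, no double counting
        assert total == pytest.approx(100.0 * 50)


class TestStandards:
    def test_lambda_fraction_profile_matched(self):
        spec = lambda_bsu36i()
        group = MoleculeGroup(
            [make_segment((10, c), (10, c + 5)) for c in (0, 10, 20)], "g0"
        )
        meas = [measurement(f) for f in (0.551, 0.157, 0.292)]
        assert identify_standards([group], [meas], spec, rel_tol=0.2) == [0]

    def test_reversed_orientation_matched(self):
        spec = lambda_bsu36i()
        group = MoleculeGroup(
            [make_segment((10, c), (10, c + 5)) for c in (0, 10, 20)], "g0"
        )
        meas = [measurement(f) for f in (14183.0, 7601.0, 26718.0)]
        assert identify_standards([group], [meas], spec) == [0]

    def test_wrong_fragment_count_rejected(self):
        spec = lambda_bsu36i()
        group = MoleculeGroup(
            [make_segment((10, c), (10, c + 5)) for c in (0, 10, 20, 30)], "g0"
        )
        meas = [measurement(1000.0)] * 4
        assert identify_standards([group], [meas], spec) == []

    def test_equal_thirds_rejected_at_default_tolerance(self):
        spec = lambda_bsu36i()
        group = MoleculeGroup(
            [make_segment((10, c), (10, c + 5)) for c in (0, 10, 20)], "g0"
        )
        meas = [measurement(1.0), measurement(1.0), measurement(1.0)]
        assert identify_standards([group], [meas], spec, rel_tol=0.2) == []


class TestConversionFactor:
    def test_worked_lambda_ratio(self):
        spec = lambda_bsu36i()
        meas = [[measurement(26718.0), measurement(7601.0), measurement(14183.0)]]
        c = estimate_conversion_factor([0], meas, spec)
        assert c.c_kb == pytest.approx(0.001)
        assert c.n_standards_used == 1

    def test_identical_standards_give_common_ratio(self):
        spec = lambda_bsu36i()
        meas = [[measurement(spec.total_kb / 0.002)] for _ in range(3)]
        # single-fragment groups are not real standards, but the ratio math
        # only uses totals
        c = estimate_conversion_factor([0, 1, 2], meas, spec)
        assert c.c_kb == pytest.approx(0.002)

    def test_median_across_standards(self):
        spec = lambda_bsu36i()
        totals = [spec.total_kb / r for r in (0.0009, 0.0010, 0.0013)]
        meas = [[measurement(t)] for t in totals]
        c = estimate_conversion_factor([0, 1, 2], meas, spec)
        assert c.c_kb == pytest.approx(0.0010)

    def test_no_standards_is_an_error_mentioning_manual_override(self):
        with pytest.raises(ValueError, match="manual c_kb"):
            estimate_conversion_factor([], [], lambda_bsu36i())

    def test_zero_fluorescence_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_conversion_factor(
                [0], [[measurement(0.0)]], lambda_bsu36i()
            )


class TestRmapConstruction:
    def _group(self, n):
        return MoleculeGroup(
            [make_segment((10, 12 * k), (10, 12 * k + 5)) for k in range(n)],
            "m1",
        )

    def test_lambda_sizes_reproduced(self):
        meas = [measurement(f) for f in (26718.0, 7601.0, 14183.0)]
        rmap = construct_rmap(self._group(3), meas, ConversionFactor(0.001))
        assert rmap.fragment_sizes_kb == pytest.approx([26.718, 7.601, 14.183])

    def test_joint_rescaling_leaves_sizes_unchanged(self):
        meas = [measurement(f) for f in (1000.0, 2500.0)]
        r1 = construct_rmap(self._group(2), meas, ConversionFactor(0.001))
        scaled = [measurement(5.0 * m.integrated_fluorescence) for m in meas]
        r2 = construct_rmap(self._group(2), scaled, ConversionFactor(0.001 / 5.0))
        assert r1.fragment_sizes_kb == pytest.approx(r2.fragment_sizes_kb)

    def test_single_fragment_group(self):
        rmap = construct_rmap(
            self._group(1), [measurement(5000.0)], ConversionFactor(0.001)
        )
        assert rmap.fragment_sizes_kb == pytest.approx([5.0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            construct_rmap(MoleculeGroup([], "x"), [], ConversionFactor(0.001))

    def test_additivity_of_group_total(self):
        meas = [measurement(f) for f in (1200.0, 3300.0, 800.0)]
        c = ConversionFactor(0.0007)
        rmap = construct_rmap(self._group(3), meas, c)
        assert rmap.total_kb == pytest.approx(
            c.c_kb * sum(m.integrated_fluorescence for m in meas)
        )


class TestFlags:
    def test_crossing_molecules_flagged_both(self):
        img = np.full((60, 60), 100.0)
        frame = Frame(img)
        a = make_segment((30, 5), (30, 50))
        b = make_segment((10, 20), (50, 40))  # crosses a near col 30
        groups = [MoleculeGroup([a], "a"), MoleculeGroup([b], "b")]
        meas = [[measurement(10.0, 300, 46)], [measurement(10.0, 300, 21)]]
        sizing.flag_distractors(groups, meas, [frame], IDENTITY, SizingParams())
        assert "distractor_overlap" in meas[0][0].flags
        assert "distractor_overlap" in meas[1][0].flags

    def test_isolated_clean_molecule_unflagged(self):
        img = np.full((60, 60), 100.0)
        img[30, 5:40] = 400.0
        frame = Frame(img)
        a = make_segment((30, 5), (30, 39))
        groups = [MoleculeGroup([a], "a")]
        meas = [[measurement(10.0, 175, 35)]]
        sizing.flag_distractors(groups, meas, [frame], IDENTITY, SizingParams())
        assert meas[0][0].flags == set()

    def test_bright_speckle_adjacent_to_fragment_flagged(self):
        img = np.full((60, 60), 100.0)
        img[30, 5:40] = 400.0
        img[32, 20] = 5000.0  # speckle inside the 2-px mask band
        frame = Frame(img)
        a = make_segment((30, 5), (30, 39))
        groups = [MoleculeGroup([a], "a")]
        meas = [[measurement(10.0, 175, 35)]]
        sizing.flag_distractors(groups, meas, [frame], IDENTITY, SizingParams())
        assert "near_bright_spot" in meas[0][0].flags

    def test_speckle_from_simulator_confuser_mode_flagged(self):
        from optmap.pipeline import PipelineConfig, process_channel
        from optmap.simulate import SimulationParams, simulate_channel

        params = SimulationParams(
            frame_shape=(260, 360),
            n_frames=3,
            molecule_density=1.0,
            size_range_kb=(20.0, 50.0),
            standards_per_channel=1,
            noise_sigma_adu=0.0,
            min_row_spacing_px=24,
            confuser_mode=True,
            seed=8,
        )
        frames, truth = simulate_channel(params)
        assert truth.speckles
        result = process_channel(frames, PipelineConfig())
        flagged = {
            flag
            for meas in result.measurements
            for m in meas
            for flag in m.flags
        }
        assert "near_bright_spot" in flagged


class TestRmapIO:
    def test_tsv_round_format(self, tmp_path):
        rmap_a = construct_rmap(
            MoleculeGroup([make_segment((10, 0), (10, 5))], "m0"),
            [measurement(5000.0)],
            ConversionFactor(0.001),
            channel_id="ch0",
        )
        meas_b = [measurement(26718.0), measurement(7601.0)]
        meas_b[1].flags.add("near_bright_spot")
        rmap_b = construct_rmap(
            MoleculeGroup(
                [make_segment((10, 0), (10, 5)), make_segment((10, 9), (10, 15))],
                "m1",
            ),
            meas_b,
            ConversionFactor(0.001),
            channel_id="ch0",
        )
        out = tmp_path / "rmaps.tsv"
        sizing.write_rmaps_tsv([rmap_a, rmap_b], out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("#")
        assert lines[1].split("\t") == ["m0", "ch0", "1", "5.000", "-"]
        assert lines[2].split("\t") == [
            "m1", "ch0", "2", "26.718", "7.601", "1:near_bright_spot",
        ]
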