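"""Ratio images, per-cell statistics, normalization and differentials."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epiredox as er
from epiredox.redox import (
    MASK_FAD_BELOW_FLOOR,
    MASK_NO_VOXELS,
    normalize_to_baseline,
    paired_shift,
    per_cell_means,
    phase_effect,
    ratio_image,
    redox_differential,
    segment_cells,
)
from epiredox.surfaces import (
    BandDirection,
    LayerBand,
    LayerProjection,
    SurfaceReference,
)
from epiredox.synthetic import (
    NoiseModel,
    RedoxModel,
    TissueModel,
    generate_stack,
    sample_cell_table,
)


def _projection(channels, n_voxels=None):
    channels = {k: np.asarray(v, dtype=float) for k, v in channels.items()}
    shape = next(iter(channels.values())).shape
    band = LayerBand(SurfaceReference.DERMIS_SURFACE, 0.0, 3.0)
    if n_voxels is None:
        n_voxels = np.ones(shape, dtype=int)
    return LayerProjection(
        {k: np.asarray(v, dtype=float) for k, v in channels.items()},
        "mean", band, n_voxels, (0.5, 0.5),
    )


class TestRatioImage:
    def test_hand_computed_example(self):
        nadph = np.array([[2.0, 4.0], [0.0, 6.0]])
        fad = np.array([[1.0, 2.0], [0.0, 3.0]])
        img = ratio_image(nadph, fad, fad_floor=0.5)
        assert img.ratio[0, 0] == pytest.approx(2.0)
        assert img.ratio[0, 1] == pytest.approx(2.0)
        assert np.isnan(img.ratio[1, 0])
        assert img.mask_reason[1, 0] == MASK_FAD_BELOW_FLOOR
        assert img.ratio[1, 1] == pytest.approx(2.0)

    def test_identity_and_all_masked(self):
        x = np.full((3, 3), 5.0)
        assert np.allclose(ratio_image(x, x, 0.0).ratio, 1.0)
        img = ratio_image(x, np.zeros((3, 3)), 0.0)
        assert np.isnan(img.ratio).all()  # fully masked, no error

    def test_nan_pixels_flagged_no_voxels(self):
        nadph = np.array([[1.0, np.nan]])
        fad = np.array([[1.0, 1.0]])
        img = ratio_image(nadph, fad, 0.0)
        assert img.mask_reason[0, 1] == MASK_NO_VOXELS

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ratio_image(np.ones((2, 2)), np.ones((3, 3)), 0.0)

    def test_equals_elementwise_loop(self):
        rng = np.random.default_rng(3)
        nadph = rng.uniform(0, 5, (6, 6))
        fad = rng.uniform(0, 5, (6, 6))
        floor = 1.0
        img = ratio_image(nadph, fad, floor)
        for y in range(6):
            for x in range(6):
                if fad[y, x] >= floor and fad[y, x] > 0:
                    assert img.ratio[y, x] == nadph[y, x] / fad[y, x]
                else:
                    assert np.isnan(img.ratio[y, x])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0))
    def test_gain_invariance(self, gain):
        """Rescaling both channels by a common detector gain leaves the
        ratio unchanged."""
        rng = np.random.default_rng(0)
        nadph = rng.uniform(0.5, 3, (4, 4))
        fad = rng.uniform(0.5, 3, (4, 4))
        a = ratio_image(nadph, fad, 0.0).ratio
        b = ratio_image(nadph * gain, fad * gain, 0.0).ratio
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestPerCellMeans:
    def test_two_pixel_hand_sum(self):
        proj = _projection({
            "NADPH": [[2.0, 4.0]],
            "FAD": [[1.0, 3.0]],
        })
        labels = np.array([[1, 1]])
        cells = per_cell_means(proj, labels, fad_floor=0.0)
        row = cells.iloc[0]
        assert row.mean_nadph == pytest.approx(3.0)
        assert row.mean_fad == pytest.approx(2.0)
        assert row.ratio == pytest.approx(1.5)  # ratio of means, not mean of ratios

    def test_uniform_intensities_unit_ratio(self):
        proj = _projection({"NADPH": np.full((3, 3), 5.0), "FAD": np.full((3, 3), 5.0)})
        cells = per_cell_means(proj, np.ones((3, 3), dtype=int), fad_floor=0.0)
        assert cells.iloc[0].ratio == pytest.approx(1.0)

    def test_cell_under_fad_floor_is_flagged(self):
        proj = _projection({"NADPH": np.ones((2, 2)), "FAD": np.full((2, 2), 0.01)})
        cells = per_cell_means(proj, np.ones((2, 2), dtype=int), fad_floor=0.5)
        assert bool(cells.iloc[0].flagged)

    def test_label_passthrough_and_shape_check(self, noise_free_mosaic):
        stack, truth = noise_free_mosaic
        res = er.quantify_stack(stack, labels=truth.label_map)
        assert np.array_equal(res.labels, truth.label_map)
        with pytest.raises(ValueError, match="shape"):
            segment_cells(res.projection, "labels_provided",
                          labels=np.zeros((3, 3), dtype=int))

    def test_auto_segmentation_matches_truth(self, noisy_mosaic):
        """Watershed auto mode recovers >=90% of planted cells 1:1 at the
        default noise preset (IoU >= 0.5 against truth labels)."""
        stack, truth = noisy_mosaic
        res = er.quantify_stack(stack)  # auto mode
        auto, truth_labels = res.labels, truth.label_map
        matched = 0
        for cid in np.unique(truth_labels[truth_labels > 0]):
            t = truth_labels == cid
            hits = auto[t]
            hits = hits[hits > 0]
            if hits.size == 0:
                continue
            best = np.bincount(hits).argmax()
            a = auto == best
            iou = (t & a).sum() / (t | a).sum()
            if iou >= 0.5:
                matched += 1
        assert matched >= 0.9 * truth.cells.shape[0]

    def test_blank_image_auto_zero_labels(self):
        proj = _projection({"NADPH": np.zeros((8, 8)), "FAD": np.zeros((8, 8))})
        labels = segment_cells(proj, "auto")
        assert labels.max() == 0


class TestNormalization:
    def _cells(self, rows):
        df = pd.DataFrame(rows)
        df["flagged"] = False
        return df

    def test_unit_mean_baseline(self):
        cells = self._cells(
            [
                {"mouse_id": "m1", "timepoint_days": 0.0, "genotype": "WT", "ratio": r}
                for r in (1.0, 1.2, 0.8)
            ]
            + [{"mouse_id": "m1", "timepoint_days": 5.0, "genotype": "WT", "ratio": 0.7}]
        )
        out = normalize_to_baseline(cells, "day0_same_mouse")
        base = out[out.timepoint_days == 0.0]
        assert base.normalized_ratio.mean() == pytest.approx(1.0)
        assert out[out.timepoint_days == 5.0].normalized_ratio.iloc[0] == pytest.approx(0.7)

    def test_scale_invariance(self):
        cells = self._cells(
            [{"mouse_id": "m1", "timepoint_days": float(d), "genotype": "WT",
              "ratio": r} for d, r in [(0, 1.0), (0, 1.5), (5, 0.9), (5, 1.1)]]
        )
        a = normalize_to_baseline(cells, "day0_same_mouse").normalized_ratio
        scaled = cells.assign(ratio=cells.ratio * 3.0)
        b = normalize_to_baseline(scaled, "day0_same_mouse").normalized_ratio
        np.testing.assert_allclose(a, b)

    def test_per_mouse_baselines_match_brute_force(self):
        rng = np.random.default_rng(1)
        rows = []
        for mouse in ("m1", "m2"):
            for day in (0.0, 5.0):
                for _ in range(5):
                    rows.append({"mouse_id": mouse, "timepoint_days": day,
                                 "genotype": "WT", "ratio": rng.uniform(0.5, 2.0)})
        cells = self._cells(rows)
        out = normalize_to_baseline(cells, "day0_same_mouse")
        for mouse in ("m1", "m2"):
            sub = cells[cells.mouse_id == mouse]
            base = sub[sub.timepoint_days == 0.0].ratio.mean()
            expected = sub.ratio / base
            got = out[out.mouse_id == mouse].normalized_ratio
            np.testing.assert_allclose(got, expected)

    def test_missing_baseline_names_mouse(self):
        cells = self._cells(
            [{"mouse_id": "m9", "timepoint_days": 5.0, "genotype": "MUTANT",
              "ratio": np.nan}]
        )
        with pytest.raises(ValueError, match="m9"):
            normalize_to_baseline(cells, "wt_cells_same_mouse")

    def test_idempotence(self):
        """Normalizing an already-normalized table with the same baseline
        leaves values unchanged."""
        cells = self._cells(
            [{"mouse_id": "m1", "timepoint_days": float(d), "genotype": "WT",
              "ratio": r} for d, r in [(0, 0.8), (0, 1.2), (5, 0.6)]]
        )
        once = normalize_to_baseline(cells, "day0_same_mouse")
        again = normalize_to_baseline(
            once.assign(ratio=once.normalized_ratio), "day0_same_mouse"
        )
        np.testing.assert_allclose(again.normalized_ratio, once.normalized_ratio)


class TestDifferentialAndShift:
    def test_identical_genotypes_unit_differential(self):
        rows = []
        for genotype in ("WT", "MUTANT"):
            for _ in range(6):
                rows.append({"mouse_id": "m1", "timepoint_days": 10.0,
                             "genotype": genotype, "ratio": 0.9, "flagged": False})
        d = redox_differential(pd.DataFrame(rows))
        assert d.differential.iloc[0] == pytest.approx(1.0)

    def test_insufficient_cells_omitted(self):
        rows = [{"mouse_id": "m1", "timepoint_days": 10.0, "genotype": "WT",
                 "ratio": 1.0, "flagged": False}] * 6
        rows += [{"mouse_id": "m1", "timepoint_days": 10.0, "genotype": "MUTANT",
                  "ratio": 0.5, "flagged": False}] * 2
        d = redox_differential(pd.DataFrame(rows), min_cells=5)
        assert len(d) == 0

    def test_paired_shift_identity_and_planted(self):
        pre = sample_cell_table(100, 1.0, mouse_id="m1", photons_per_cell=0)
        post = sample_cell_table(100, 1.30, mouse_id="m1", photons_per_cell=0)
        shift = paired_shift(pre, post)
        assert shift.shift_percent.iloc[0] == pytest.approx(30.0)
        same = paired_shift(pre, pre)
        assert same.shift_percent.iloc[0] == pytest.approx(0.0)

    def test_paired_shift_unmatched_mouse(self):
        pre = sample_cell_table(5, 1.0, mouse_id="m1", photons_per_cell=0)
        post = sample_cell_table(5, 1.3, mouse_id="m2", photons_per_cell=0)
        with pytest.raises(ValueError, match="unmatched"):
            paired_shift(pre, post)


class TestPhaseEffect:
    def _table(self, boost, n=60, seed=0, photons=0.0):
        rng = np.random.default_rng(seed)
        frames = []
        for mouse in ("m1", "m2", "m3"):
            n_g1 = int(0.8 * n)
            frames.append(sample_cell_table(n_g1, boost, mouse_id=mouse,
                                            phase="G1", rng=rng,
                                            photons_per_cell=photons))
            frames.append(sample_cell_table(n - n_g1, 1.0, mouse_id=mouse,
                                            phase="SG2", rng=rng,
                                            photons_per_cell=photons))
        return pd.concat(frames, ignore_index=True)

    def test_noise_free_boost_recovered(self):
        per_mouse, _ = phase_effect(self._table(1.1, n=40) .assign(
            mean_nadph=lambda d: d.ratio))
        np.testing.assert_allclose(per_mouse.g1_over_sg2, 1.1, rtol=1e-12)

    def test_null_boost_flat(self):
        table = self._table(1.0)
        table["mean_nadph"] = table.ratio
        per_mouse, result = phase_effect(table)
        assert result.p_value > 0.2
        np.testing.assert_allclose(per_mouse.g1_over_sg2, 1.0, rtol=1e-9)

    def test_single_phase_raises(self):
        table = self._table(1.1)
        table["phase"] = "G1"
        with pytest.raises(ValueError, match="both phases"):
            phase_effect(table)

    def test_direction_detected_in_replicates(self):
        """G1 > S/G2 NAD(P)H direction detected in >=95% of 100 seeded
        replicates at the default photon budget (3 mice x 200 cells)."""
        rng = np.random.default_rng(123)
        detected = 0
        for _ in range(100):
            frames = []
            for mouse in ("m1", "m2", "m3"):
                frames.append(sample_cell_table(160, 1.1, mouse_id=mouse,
                                                phase="G1", rng=rng))
                frames.append(sample_cell_table(40, 1.0, mouse_id=mouse,
                                                phase="SG2", rng=rng))
            table = pd.concat(frames, ignore_index=True)
            table["mean_nadph"] = table.ratio * table.mean_fad
            per_mouse, _ = phase_effect(table)
            if (per_mouse.g1_over_sg2 > 1.0).all():
                detected += 1
        assert detected >= 95
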