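"""Organizer ROI scheme, composite averaging and compartment traces."""

import numpy as np
import pytest

from fretkin.fret_core import EfficiencyStack
from fretkin.roi_regions import (circle_mask, compartment_traces,
                                 extract_trace, make_roi_scheme,
                                 organizer_traces)
from fretkin.synthetic_scene import true_eta


def _scheme(shape=(256, 256), center=(128, 128), spacing=30.0, diameter=20.0):
    return make_roi_scheme(center, ap_direction=(1, 0), dv_direction=(0, 1),
                           pixel_size_um=1.0, image_shape=shape,
                           spacing_um=spacing, diameter_um=diameter)


def _stack(eta_maps, interval=1.0):
    eta_maps = np.asarray(eta_maps, dtype=float)
    return EfficiencyStack(eta=eta_maps, valid=np.isfinite(eta_maps),
                           times_min=interval * np.arange(eta_maps.shape[0]))


class TestMakeRoiScheme:
    def test_axis_aligned_geometry(self):
        scheme = _scheme()
        assert scheme.circles["APB1"] == (98.0, 128.0)
        assert scheme.circles["APB2"] == (128.0, 128.0)
        assert scheme.circles["APB3"] == (158.0, 128.0)
        assert scheme.circles["DVB1"] == (128.0, 98.0)
        assert scheme.circles["DVB3"] == (128.0, 158.0)

    def test_nine_circles_five_distinct_organizer(self):
        scheme = _scheme()
        assert len(scheme.circles) == 10  # 9 circles; APB2/DVB2 share a center
        assert scheme.circles["APB2"] == scheme.circles["DVB2"]
        distinct = {scheme.circles[r] for r in
                    ("APB1", "APB2", "APB3", "DVB1", "DVB2", "DVB3")}
        assert len(distinct) == 5
        assert len({scheme.circles[f"NO{i}"] for i in range(1, 5)}) == 4

    def test_zero_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            _scheme(spacing=0.0)

    def test_parallel_directions_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            make_roi_scheme((10, 10), (1, 0), (-2, 0), 1.0, (64, 64))

    def test_out_of_bounds_circle_named(self):
        with pytest.raises(ValueError, match="APB1"):
            _scheme(shape=(64, 64), center=(32, 32), spacing=30.0)


class TestExtractTrace:
    def test_uniform_stack_traces_constant(self):
        scheme = _scheme()
        stack = _stack(np.full((4, 256, 256), 0.5))
        for trace in organizer_traces(stack, scheme).values():
            np.testing.assert_allclose(trace.mean_eta, 0.5)

    def test_composite_is_roi_mean_of_means(self):
        """ORG trace: mean of 5 circle means, not a pooled pixel mean.

        Equal-area circles on a smooth image make the two aggregations
        coincide, so invalid pixels are punched into one circle to break
        the valid-area symmetry; the documented ROI-wise mean must hold.
        """
        scheme = _scheme()
        img = np.tile(np.linspace(0, 1, 256), (256, 1))
        holes = circle_mask((256, 256), scheme.circles["DVB1"], 6)
        img[holes] = np.nan
        stack = _stack(img[None])
        org = extract_trace(stack, scheme.composite("ORG"), label="ORG")
        # brute-force both aggregations over valid pixels only
        masks = [circle_mask((256, 256), scheme.circles[r], scheme.radius_px)
                 for r in ("APB1", "APB2", "APB3", "DVB1", "DVB3")]
        mean_of_means = np.mean([np.nanmean(img[m]) for m in masks])
        union = np.any(masks, axis=0)
        pooled = np.nanmean(img[union])
        assert org.mean_eta[0] == pytest.approx(mean_of_means, abs=1e-12)
        assert abs(mean_of_means - pooled) > 1e-5  # the two differ here
        assert org.mean_eta[0] != pytest.approx(pooled, abs=1e-6)

    def test_equal_area_rois_on_uniform_image_match_pooled(self):
        scheme = _scheme()
        stack = _stack(np.full((1, 256, 256), 0.42))
        no = extract_trace(stack, scheme.composite("NO"), label="NO")
        pooled_mask = np.any([scheme.mask(f"NO{i}") for i in range(1, 5)], axis=0)
        pooled = extract_trace(stack, pooled_mask, label="NO_pooled")
        assert no.mean_eta[0] == pytest.approx(pooled.mean_eta[0], abs=1e-12)

    def test_empty_region_rejected(self):
        stack = _stack(np.full((2, 16, 16), 0.5))
        with pytest.raises(ValueError, match="empty"):
            extract_trace(stack, np.zeros((16, 16), bool), label="nothing")

    def test_all_invalid_frames_are_missing(self):
        eta = np.full((3, 16, 16), 0.5)
        eta[1] = np.nan
        stack = _stack(eta)
        mask = circle_mask((16, 16), (8, 8), 3)
        tr = extract_trace(stack, mask, label="c")
        assert np.isnan(tr.mean_eta[1]) and tr.n_valid[1] == 0

    def test_padding_invariance(self):
        mask = circle_mask((32, 32), (16, 16), 5)
        eta = np.random.default_rng(0).uniform(0.2, 0.8, (3, 32, 32))
        tr = extract_trace(_stack(eta), mask, label="c")
        padded = np.pad(eta, ((0, 0), (0, 8), (0, 8)), constant_values=np.nan)
        mask_p = np.pad(mask, ((0, 8), (0, 8)))
        tr_p = extract_trace(_stack(padded), mask_p, label="c")
        np.testing.assert_allclose(tr.mean_eta, tr_p.mean_eta, atol=1e-15)

    def test_slow_region_stays_above_fast_region(self, noiseless_scene,
                                                 noiseless_eta):
        """APB (t1/2 45) never drops below NO (t1/2 30) after the drug."""
        spec, labels, truth, _ = noiseless_scene
        apb = extract_trace(noiseless_eta, labels.masks["APB"], label="APB")
        no = extract_trace(noiseless_eta, labels.masks["NO"], label="NO")
        post = apb.times_min > spec.drug_time_min
        assert np.all(apb.mean_eta[post] >= no.mean_eta[post])

    def test_noiseless_traces_match_generating_curves(self, noiseless_scene,
                                                      noiseless_eta):
        spec, labels, truth, _ = noiseless_scene
        t_since = np.maximum(spec.times_min - spec.drug_time_min, 0.0)
        for region in ("APB", "DVB", "NO_DA", "NO_VP"):
            mask = labels.masks[region]
            if region in ("APB", "DVB"):
                mask = mask & ~labels.masks["ORG"]
            tr = extract_trace(noiseless_eta, mask, label=region)
            kin = truth.kinetics[region]
            expected = np.where(spec.times_min > spec.drug_time_min,
                                true_eta(kin, t_since), kin.max_eta)
            np.testing.assert_allclose(tr.mean_eta, expected, atol=1e-9)


class TestCompartmentTraces:
    @staticmethod
    def _scheme_with_polygons(shape=(64, 64)):
        h, w = shape
        scheme = make_roi_scheme((h / 2, w / 2), (1, 0), (0, 1), 1.0, shape,
                                 spacing_um=10.0, diameter_um=6.0)
        split = h / 2 - 0.5  # between the pixel rows either side of the DV line
        dorsal = [[-0.5, -0.5], [-0.5, w - 0.5], [split, w - 0.5], [split, -0.5]]
        ventral = [[split, -0.5], [split, w - 0.5],
                   [h - 0.5, w - 0.5], [h - 0.5, -0.5]]
        return scheme.__class__(
            circles=scheme.circles, diameter_um=scheme.diameter_um,
            pixel_size_um=1.0, image_shape=shape,
            dorsal_polygon=np.array(dorsal), ventral_polygon=np.array(ventral),
            ap_line=scheme.ap_line)

    def test_compartments_partition_pouch(self):
        scheme = self._scheme_with_polygons()
        stack = _stack(np.full((2, 64, 64), 0.5))
        traces = compartment_traces(stack, scheme)
        from fretkin.roi_regions import _polygon_mask
        d = _polygon_mask((64, 64), scheme.dorsal_polygon, "d")
        v = _polygon_mask((64, 64), scheme.ventral_polygon, "v")
        assert d.sum() + v.sum() == 64 * 64
        assert not (d & v).any()
        assert set(traces) == {"D", "V", "DA", "DP", "VA", "VP"}

    def test_subcompartments_partition_compartment(self):
        scheme = self._scheme_with_polygons()
        eta = np.random.default_rng(3).uniform(0.2, 0.8, (1, 64, 64))
        stack = _stack(eta)
        traces = compartment_traces(stack, scheme)
        from fretkin.roi_regions import _polygon_mask
        d = _polygon_mask((64, 64), scheme.dorsal_polygon, "d")
        point, direction = scheme.ap_line
        rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        anterior = (direction[0] * (cc - point[1])
                    - direction[1] * (rr - point[0])) < 0
        da, dp = d & anterior, d & ~anterior
        assert (da | dp).sum() == d.sum() and not (da & dp).any()
        pooled_d = (traces["DA"].mean_eta * da.sum()
                    + traces["DP"].mean_eta * dp.sum()) / d.sum()
        np.testing.assert_allclose(pooled_d, traces["D"].mean_eta, atol=1e-12)

    def test_uniform_stack_all_traces_equal(self):
        scheme = self._scheme_with_polygons()
        stack = _stack(np.full((3, 64, 64), 0.61))
        for trace in compartment_traces(stack, scheme).values():
            np.testing.assert_allclose(trace.mean_eta, 0.61)

    def test_degenerate_polygon_rejected(self):
        scheme = self._scheme_with_polygons()
        bad = scheme.__class__(
            circles=scheme.circles, diameter_um=scheme.diameter_um,
            pixel_size_um=1.0, image_shape=scheme.image_shape,
            dorsal_polygon=np.array([[0, 0], [1, 1]]),
            ventral_polygon=scheme.ventral_polygon, ap_line=scheme.ap_line)
        with pytest.raises(ValueError, match="vertices"):
            compartment_traces(_stack(np.full((1, 64, 64), 0.5)), bad)
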