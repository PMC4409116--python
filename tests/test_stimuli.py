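"""Gabor stimulus construction: luminance profile, paths, assembly rules."""

import math

import numpy as np
import pytest

from ermkit import (
    GaborParams,
    StimulusSpec,
    StimulusWithdrawn,
    assemble_stimulus,
    build_contour_path,
    gabor_luminance,
    generate_ct_nct_pair,
    generate_stimulus,
    make_noncontour,
    render_luminance,
)


def orientation_diff(a, b):
    """Circular difference between orientations in [0, 180)."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


class TestGaborLuminance:
    def test_carrier_zero_crossing_at_origin(self):
        for theta in (0.0, 17.0, 90.0, 135.0):
            p = GaborParams(orientation=theta)
            assert gabor_luminance((0.0, 0.0), p) == pytest.approx(1.0)

    def test_envelope_vanishes_far_away(self):
        p = GaborParams()
        r = 10 * p.envelope_sd
        val = gabor_luminance((r / math.sqrt(2), r / math.sqrt(2)), p)
        assert abs(val - p.background_luminance) <= 1e-10 * p.background_luminance * p.contrast

    def test_quarter_period_point_vertical_grating(self):
        # theta=0, f=3 cpd: the carrier argument is 2*pi*f*x, which equals
        # pi/2 at x = 1/(4f); there L = L0*(1 + C*exp(-x^2/(2 sigma^2)))
        p = GaborParams(contrast=0.9, spatial_freq=3.0, envelope_sd=0.25,
                        background_luminance=1.0, orientation=0.0)
        x = 1.0 / (4.0 * p.spatial_freq)
        expected = 1.0 * (1.0 + 0.9 * math.exp(-x**2 / (2.0 * 0.25**2)))
        assert gabor_luminance((x, 0.0), p) == pytest.approx(expected, abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GaborParams(contrast=1.5)
        with pytest.raises(ValueError):
            GaborParams(spatial_freq=0.0)


class TestSpecGeometry:
    def test_cell_size_formula(self):
        spec = StimulusSpec(element_separation=2.0)
        assert round(spec.cell_size, 2) == 1.66

    def test_field_extent_matches_grid(self):
        spec = StimulusSpec()
        assert spec.field_extent == pytest.approx(10 * spec.cell_size)


class TestContourPath:
    def test_straight_path_is_collinear(self, rng):
        spec = StimulusSpec(path_angle=0.0, orientation_jitter_bound=0.0)
        path = build_contour_path(spec, rng)
        assert len(path) == 10
        for a, b in zip(path, path[1:]):
            assert orientation_diff(a.orientation, b.orientation) == pytest.approx(0.0, abs=1e-9)

    def test_constant_turn_without_jitter(self, rng):
        spec = StimulusSpec(path_angle=30.0, orientation_jitter_bound=0.0)
        path = build_contour_path(spec, rng)
        for a, b in zip(path, path[1:]):
            assert orientation_diff(a.orientation, b.orientation) == pytest.approx(30.0, abs=1e-9)

    def test_placement_constraints_and_separation(self, stim_spec):
        rng = np.random.default_rng(7)
        inner2 = {(r, c) for r in (4, 5) for c in (4, 5)}
        inner6 = {(r, c) for r in range(2, 8) for c in range(2, 8)}
        for _ in range(100):
            path = build_contour_path(stim_spec, rng)
            cells = [stim_spec.cell_of(e.center_x, e.center_y) for e in path]
            assert not any(c in inner2 for c in cells)
            assert sum(c in inner6 for c in cells) >= 4
            for a, b in zip(path, path[1:]):
                sep = math.hypot(a.center_x - b.center_x, a.center_y - b.center_y)
                assert 1.45 - 1e-9 <= sep <= 2.55 + 1e-9


class TestAssembly:
    def test_element_count_in_range(self, stim_spec):
        rng = np.random.default_rng(3)
        for _ in range(20):
            field = generate_stimulus(stim_spec, rng)
            assert 90 <= field.n_elements <= 100
            assert sum(e.on_path for e in field.elements) == 10

    def test_nct_preserves_geometry_rotates_path(self, stim_spec):
        rng = np.random.default_rng(5)
        ct, nct = generate_ct_nct_pair(stim_spec, rng)
        assert nct.n_elements == ct.n_elements
        assert nct.condition == "NCT"
        for e_ct, e_nct in zip(ct.elements, nct.elements):
            assert (e_ct.center_x, e_ct.center_y) == (e_nct.center_x, e_nct.center_y)
            if e_ct.on_path:
                assert orientation_diff(e_ct.orientation, e_nct.orientation) == pytest.approx(45.0)
            else:
                assert e_ct.orientation == e_nct.orientation

    def test_seeded_reproducibility(self, stim_spec):
        f1 = generate_stimulus(stim_spec, np.random.default_rng(99))
        f2 = generate_stimulus(stim_spec, np.random.default_rng(99))
        assert f1.elements == f2.elements

    def test_withdrawal_when_elements_cannot_be_drawn(self, rng):
        # an oversized visible disk makes neighbouring cells collide constantly
        spec = StimulusSpec(path_angle=25.0, visible_radius=1.4)
        path = build_contour_path(spec, rng)
        with pytest.raises(StimulusWithdrawn):
            assemble_stimulus(path, spec, rng)

    def test_nct_requires_ct_field(self, stim_spec, rng):
        field = generate_stimulus(stim_spec, rng)
        nct = make_noncontour(field, rng)
        with pytest.raises(ValueError):
            make_noncontour(nct, rng)


class TestRendering:
    def test_raster_shape_and_range(self, stim_spec):
        rng = np.random.default_rng(17)
        field = generate_stimulus(stim_spec, rng)
        raster = render_luminance(field, GaborParams(), resolution=10.0)
        n = int(round(spec_extent := stim_spec.field_extent * 10.0))
        assert raster.shape == (n, n)
        assert np.isfinite(raster).all()
        # luminance modulates around the background level
        assert raster.max() > 1.0 > raster.min()

    def test_isolated_element_matches_pointwise_formula(self):
        spec = StimulusSpec()
        from ermkit.stimuli import GaborElement, GaborField
        el = GaborElement(0.0, 0.0, 30.0, on_path=False)
        field = GaborField(elements=[el], condition="CT", spec=spec)
        params = GaborParams(orientation=30.0)
        res = 20.0
        raster = render_luminance(field, GaborParams(), resolution=res)
        n = raster.shape[0]
        coords = (np.arange(n) + 0.5) / res - spec.field_extent / 2.0
        i = n // 2
        expected = gabor_luminance((coords[i], coords[i]), params)
        assert raster[i, i] == pytest.approx(expected, abs=1e-12)
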