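"""PIV estimation, accumulation and curve reduction against known motion."""

import numpy as np
import pytest

from contractile_escape import (
    DisplacementField,
    DisplacementSeries,
    FieldSpec,
    PIVSettings,
    accumulate,
    displacement_curve,
    displacement_rate,
    estimate_frame_displacement,
    estimate_sequence,
    explant_roi,
    make_collagen_sequence,
)
from contractile_escape.piv import read_fields_csv, write_fields_csv

from conftest import interior, warp_frame


def constant_field(ux=1.0, uy=0.0, n=5):
    gx = np.arange(n, dtype=float) * 10
    gy = np.arange(n, dtype=float) * 10
    return DisplacementField(
        grid_x=gx,
        grid_y=gy,
        ux=np.full((n, n), ux),
        uy=np.full((n, n), uy),
        valid=np.ones((n, n), dtype=bool),
    )


class TestFrameDisplacement:
    def test_identical_frames_give_zero_field(self, speckle_frame, piv_settings):
        f = estimate_frame_displacement(speckle_frame, speckle_frame, piv_settings)
        assert np.allclose(f.ux[f.valid], 0.0, atol=1e-6)
        assert np.allclose(f.uy[f.valid], 0.0, atol=1e-6)

    def test_integer_shift_recovered_in_physical_units(self, speckle_frame, piv_settings):
        shifted = warp_frame(speckle_frame, 3.0)
        f = estimate_frame_displacement(speckle_frame, shifted, piv_settings, pixel_size=4.0)
        sel = interior(f.valid) & f.valid
        assert np.abs(f.ux[sel] - 12.0).max() < 0.2  # um
        assert np.abs(f.uy[sel]).max() < 0.2

    @pytest.mark.parametrize("shift", [2.6, 0.5])
    def test_fractional_shift_subpixel(self, speckle_frame, piv_settings, shift):
        shifted = warp_frame(speckle_frame, shift)
        f = estimate_frame_displacement(speckle_frame, shifted, piv_settings)
        sel = interior(f.valid) & f.valid
        assert np.abs(f.ux[sel] - shift).max() < 0.2

    def test_shape_mismatch_rejected(self, speckle_frame, piv_settings):
        with pytest.raises(ValueError):
            estimate_frame_displacement(speckle_frame, speckle_frame[:-1], piv_settings)

    def test_constant_frames_flagged_invalid(self, piv_settings):
        flat = np.full((64, 64), 17.0)
        f = estimate_frame_displacement(flat, flat, piv_settings)
        assert not f.valid.any()

    def test_radial_increments_rms_below_tolerance(self):
        # generator-truth oracle: per-step vector RMS error < 0.15 px
        seq, inc, _ = make_collagen_sequence(
            FieldSpec(rate=8.0), n_frames=11, frame_interval=0.25
        )
        est = estimate_sequence(seq)
        err2 = [
            ((e.ux - t.ux) ** 2 + (e.uy - t.uy) ** 2) / seq.pixel_size**2
            for e, t in zip(est, inc)
        ]
        assert np.sqrt(np.mean(err2)) < 0.15


class TestAccumulate:
    def test_linearity_constant_fields(self):
        fields = [constant_field(2.0, -1.0) for _ in range(4)]
        cum = accumulate(fields)
        assert np.allclose(cum[-1].ux, 8.0)
        assert np.allclose(cum[-1].uy, -4.0)

    def test_single_field_is_identity(self):
        f = constant_field(1.5, 0.5)
        cum = accumulate([f])
        assert np.allclose(cum[0].ux, f.ux)

    def test_reordering_preserves_final_sum(self):
        rng = np.random.default_rng(3)
        fields = []
        for _ in range(5):
            f = constant_field()
            f.ux = rng.normal(size=f.ux.shape)
            f.uy = rng.normal(size=f.uy.shape)
            fields.append(f)
        a = accumulate(fields)[-1]
        b = accumulate(fields[::-1])[-1]
        assert np.allclose(a.ux, b.ux) and np.allclose(a.uy, b.uy)

    def test_invalid_vectors_contribute_zero_and_flag_imputed(self):
        f1, f2 = constant_field(2.0), constant_field(2.0)
        f2.valid[1, 1] = False
        cum = accumulate([f1, f2])
        assert cum[-1].ux[1, 1] == 2.0
        assert cum[-1].imputed[1, 1]
        assert not cum[-1].imputed[0, 0]

    def test_grid_mismatch_rejected(self):
        f2 = constant_field()
        f2.grid_x = f2.grid_x + 1.0
        with pytest.raises(ValueError):
            accumulate([constant_field(), f2])


class TestDisplacementCurve:
    def test_zero_fields_give_zero_curve(self):
        cum = accumulate([constant_field(0.0, 0.0)] * 3)
        s = displacement_curve(cum, R0=100.0)
        assert np.allclose(s.normalized, 0.0)

    def test_uniform_magnitude_normalization(self):
        cum = [constant_field(10.0, 0.0)]
        s = displacement_curve(cum, R0=100.0)
        assert s.normalized[0] == pytest.approx(0.1)

    def test_normalization_scales_inversely_with_r0(self):
        cum = [constant_field(7.0, 0.0)]
        a = displacement_curve(cum, R0=50.0).normalized[0]
        b = displacement_curve(cum, R0=100.0).normalized[0]
        assert a == pytest.approx(2 * b)

    def test_explant_roi_side_is_three_r0(self):
        roi = explant_roi((500.0, 400.0), R0=206.0)
        assert roi.side == pytest.approx(618.0)

    def test_empty_roi_rejected(self):
        from contractile_escape import SquareRoi

        with pytest.raises(ValueError, match="ROI"):
            displacement_curve([constant_field()], R0=10.0, roi=SquareRoi((1e6, 1e6), 1.0))


class TestDisplacementRate:
    def test_exact_line_slope(self):
        t = np.arange(10.0)
        s = DisplacementSeries(times=t, mean_mag=0.82 * t, R0=100.0)
        assert displacement_rate(s) == pytest.approx(0.82)

    def test_constant_series_zero_rate(self):
        s = DisplacementSeries(times=np.arange(5.0), mean_mag=np.full(5, 3.0), R0=100.0)
        assert displacement_rate(s) == pytest.approx(0.0)

    def test_degenerate_time_vector_rejected(self):
        s = DisplacementSeries(times=np.zeros(3), mean_mag=np.zeros(3), R0=1.0)
        with pytest.raises(ValueError):
            displacement_rate(s)


def test_fields_csv_round_trip(tmp_path):
    fields = accumulate([constant_field(1.25, -0.5)] * 2)
    path = tmp_path / "fields.csv"
    write_fields_csv(fields, [0.25, 0.5], path)
    back, times = read_fields_csv(path)
    assert np.allclose(times, [0.25, 0.5])
    assert np.allclose(back[1].ux, fields[1].ux, atol=1e-4)
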