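"""Generator ground-truth contracts: field shape, determinism, warp fidelity,
area truth, cohort composition."""

import numpy as np
import pytest

from contractile_escape import (
    FieldSpec,
    NoiseSpec,
    SLSParams,
    SpreadMode,
    StretchProtocol,
    creep_response,
    eval_field,
    make_collagen_sequence,
    make_hertz_curve,
    make_population,
    make_spreading_sequence,
    make_stretcher_trace,
    make_translation_sequence,
)


class TestEvalField:
    def test_zero_time_gives_zero_vector(self):
        spec = FieldSpec(rate=0.5, center=(0.0, 0.0))
        assert np.allclose(eval_field(spec, (40.0, 70.0), 0.0), 0.0)

    def test_edge_magnitude_matches_rate_times_time(self):
        # 0.82 um/h for 60 h at the spheroid edge -> 49.2 um, pointing inward
        spec = FieldSpec(rate=0.82, edge_radius=100.0, center=(0.0, 0.0))
        u = eval_field(spec, (100.0, 0.0), 60.0)
        assert np.hypot(*u) == pytest.approx(49.2, abs=1e-9)
        assert u[0] < 0 and u[1] == pytest.approx(0.0)

    def test_center_point_gets_zero_vector(self):
        spec = FieldSpec(rate=1.0, center=(50.0, 50.0))
        assert np.allclose(eval_field(spec, (50.0, 50.0), 10.0), 0.0)

    def test_magnitude_non_increasing_beyond_edge(self):
        spec = FieldSpec(rate=1.0, edge_radius=80.0, decay_length=50.0, center=(0.0, 0.0))
        d = np.linspace(80, 400, 30)
        pts = np.column_stack([d, np.zeros_like(d)])
        mags = np.hypot(*eval_field(spec, pts, 5.0).T)
        assert np.all(np.diff(mags) <= 1e-12)


class TestCollagenSequence:
    def test_zero_rate_gives_identical_frames(self):
        seq, inc, cum = make_collagen_sequence(FieldSpec(rate=0.0), n_frames=4)
        assert all(np.array_equal(seq.frames[0], f) for f in seq.frames[1:])
        assert all(np.allclose(f.magnitude, 0) for f in inc + cum)

    def test_integer_translation_equals_rolled_frames(self):
        # warp fidelity: integer uniform shift equals np.roll away from the border
        seq = make_translation_sequence((3.0, 0.0), n_frames=4)
        for k in range(1, 4):
            rolled = np.roll(seq.frames[0], 3 * k, axis=1)
            assert np.array_equal(seq.frames[k][:, 3 * k :], rolled[:, 3 * k :])

    def test_cumulative_truth_is_sum_of_incremental_truth(self):
        _, inc, cum = make_collagen_sequence(FieldSpec(rate=0.5), n_frames=6)
        sx = np.zeros_like(inc[0].ux)
        sy = np.zeros_like(inc[0].uy)
        for i, c in zip(inc, cum):
            sx += i.ux
            sy += i.uy
            assert np.allclose(sx, c.ux, atol=1e-9)
            assert np.allclose(sy, c.uy, atol=1e-9)

    def test_edge_cumulative_magnitude_matches_formula(self):
        # 0.24 um/h over 60 h -> 14.4 um at the spheroid edge (analytic field)
        spec = FieldSpec(rate=0.24, edge_radius=100.0, center=(0.0, 0.0))
        u = eval_field(spec, (100.0, 0.0), 240 * 0.25)
        assert np.hypot(*u) == pytest.approx(14.4, abs=1e-9)

    def test_seed_determinism(self):
        a, _, _ = make_collagen_sequence(FieldSpec(rate=0.3), n_frames=3, noise=NoiseSpec(2.0, 7))
        b, _, _ = make_collagen_sequence(FieldSpec(rate=0.3), n_frames=3, noise=NoiseSpec(2.0, 7))
        assert np.array_equal(a.frames, b.frames)


class TestSpreadingSequence:
    def test_compact_area_is_constant(self):
        _, truth = make_spreading_sequence(SpreadMode("compact"), n_frames=5)
        assert np.all(truth.areas == truth.areas[0])

    def test_area_truth_equals_mask_pixel_count(self):
        _, truth = make_spreading_sequence(
            SpreadMode("wetting", area_rate=0.05), n_frames=5, pixel_size=4.0
        )
        assert np.array_equal(truth.areas, truth.masks.sum(axis=(1, 2)) * 16.0)

    @pytest.mark.parametrize(
        "mode,rate,t_expect,ratio",
        [("wetting", 0.031, 60, 2.86), ("evaporation", 0.162, 10, 2.62)],
    )
    def test_area_ratio_tracks_rate(self, mode, rate, t_expect, ratio):
        _, truth = make_spreading_sequence(
            SpreadMode(mode, area_rate=rate),
            n_frames=t_expect + 1,
            frame_interval=1.0,
            shape=(384, 384),
        )
        assert truth.areas[t_expect] / truth.areas[0] == pytest.approx(ratio, rel=0.03)

    def test_disk_leaving_frame_raises(self):
        with pytest.raises(ValueError, match="leaves the frame"):
            make_spreading_sequence(
                SpreadMode("wetting", area_rate=0.5), R0=200.0, n_frames=40, shape=(128, 128)
            )

    def test_compact_with_nonzero_rate_rejected(self):
        with pytest.raises(ValueError):
            SpreadMode("compact", area_rate=0.1)


class TestStretcherTraces:
    def test_passive_trace_equals_sls_creep(self):
        p = SLSParams(40.0, 40.0, 60.0, sigma_int=0.0)
        prot = StretchProtocol()
        tr = make_stretcher_trace(p, prot, NoiseSpec(0.0, 0))
        assert np.allclose(tr.strain, creep_response(p, prot, tr.times))

    def test_contraction_beats_pull_strain_decreases(self):
        # sigma_int above sigma0: deformation must fall near the end of stretch
        p = SLSParams(40.0, 40.0, 60.0, sigma_int=1.09, t_on=2.0)
        prot = StretchProtocol(sigma0=1.0)
        tr = make_stretcher_trace(p, prot, NoiseSpec(0.0, 0))
        end = prot.t_trap1 + prot.t_stretch
        sel = (tr.times > end - 0.5) & (tr.times <= end)
        assert np.all(np.diff(tr.strain[sel]) < 0)

    def test_same_seed_identical_traces(self):
        p = SLSParams(40.0, 40.0, 60.0, 0.5, 2.0)
        a = make_stretcher_trace(p, noise=NoiseSpec(0.003, 5))
        b = make_stretcher_trace(p, noise=NoiseSpec(0.003, 5))
        assert np.array_equal(a.strain, b.strain)


class TestPopulation:
    def test_single_class_cohort(self):
        _, truth, labels = make_population((1.0, 0.0, 0.0), 10, seed=0)
        assert len(truth) == 10
        assert all(p.sigma_int < 0.1 for p in truth)
        assert labels == ["non"] * 10

    def test_cac1_rounding_gives_239_128_79(self):
        _, truth, labels = make_population((0.5359, 0.2862, 0.1779), 446, seed=1)
        assert labels.count("non") == 239
        assert labels.count("moderate") == 128
        assert labels.count("high") == 79

    def test_all_high_band(self):
        _, truth, _ = make_population((0.0, 0.0, 1.0), 3, seed=2)
        assert all(p.sigma_int > 0.8 for p in truth)

    def test_zero_fractions_rejected(self):
        with pytest.raises(ValueError):
            make_population((0.0, 0.0, 0.0), 5)


class TestHertzCurve:
    def test_zero_indentation_zero_force(self):
        c = make_hertz_curve(500.0, contact_offset=0.0)
        assert c.force[np.isclose(c.indentation, 0.0, atol=1e-9)] == pytest.approx(0.0)
        assert c.force[c.indentation <= 0].max() == 0.0

    def test_incompressible_nu_rejected_by_generator(self):
        with pytest.raises(ValueError):
            make_hertz_curve(500.0, nu=0.5)

    def test_seed_determinism(self):
        a = make_hertz_curve(300.0, noise=NoiseSpec(0.05, 9))
        b = make_hertz_curve(300.0, noise=NoiseSpec(0.05, 9))
        assert np.array_equal(a.force, b.force)
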