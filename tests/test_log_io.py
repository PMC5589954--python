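import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmargin import (
    BeamIntervals,
    ImagingSeries,
    ModelerTrace,
    TrackingBundle,
    gate_to_beam_on,
    parse_bundle,
    to_patient_frame,
    write_bundle,
)
from lungmargin.log_io import FrameError, LogParseError, rotate_positions


def bundles_equal(a: TrackingBundle, b: TrackingBundle, atol=1e-9) -> bool:
    for name in ("imaging", "modeler", "predictor"):
        sa, sb = getattr(a, name), getattr(b, name)
        if not (np.allclose(sa.t, sb.t, atol=atol) and np.allclose(sa.pos, sb.pos, atol=atol)):
            return False
    return np.allclose(a.beam.intervals, b.beam.intervals, atol=atol)


class TestDialectRoundTrip:
    def test_writer_parser_inverse(self, noisy_fraction, tmp_path):
        _, bundle = noisy_fraction
        write_bundle(bundle, tmp_path)
        back = parse_bundle(tmp_path, patient_id=bundle.patient_id,
                            fraction_id=bundle.fraction_id)
        assert bundles_equal(bundle, back, atol=1e-5)  # %.6f serialization

    def test_three_line_imaging_file_echoed(self, tmp_path):
        (tmp_path / "modelpoints.csv").write_text(
            "time_s,si_mm,lr_mm,ap_mm\n40,1.5,-2.25,0.125\n80,2.5,0,-1\n120,0,0,3\n"
        )
        for name, body in (
            ("modeler.csv", "time_s,si_mm,lr_mm,ap_mm\n0,0,0,0\n130,0,0,0\n"),
            ("predictor.csv", "time_s,si_mm,lr_mm,ap_mm\n0,0,0,0\n130,0,0,0\n"),
            ("beam.csv", "start_s,end_s\n0,130\n"),
        ):
            (tmp_path / name).write_text(body)
        bundle = parse_bundle(tmp_path)
        assert len(bundle.imaging) == 3
        np.testing.assert_array_equal(bundle.imaging.t, [40, 80, 120])
        np.testing.assert_array_equal(
            bundle.imaging.pos, [[1.5, -2.25, 0.125], [2.5, 0, -1], [0, 0, 3]]
        )

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_bundle(tmp_path)

    def test_few_malformed_lines_skipped_with_warning(self, tmp_path, noisy_fraction):
        _, bundle = noisy_fraction
        write_bundle(bundle, tmp_path)
        path = tmp_path / "modeler.csv"
        lines = path.read_text().splitlines()
        lines.insert(100, "garbage,not,a,number")
        path.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="malformed"):
            back = parse_bundle(tmp_path)
        assert len(back.modeler) == len(bundle.modeler)

    def test_too_many_malformed_lines_raise_with_line_numbers(self, tmp_path):
        (tmp_path / "modelpoints.csv").write_text(
            "time_s,si_mm,lr_mm,ap_mm\n1,0,0,0\nbad,line,x,y\nworse\n2,0,0,0\n"
        )
        for name, body in (
            ("modeler.csv", "time_s,si_mm,lr_mm,ap_mm\n0,0,0,0\n3,0,0,0\n"),
            ("predictor.csv", "time_s,si_mm,lr_mm,ap_mm\n0,0,0,0\n3,0,0,0\n"),
            ("beam.csv", "start_s,end_s\n0,3\n"),
        ):
            (tmp_path / name).write_text(body)
        with pytest.raises(LogParseError, match=r"lines 3, 4"):
            parse_bundle(tmp_path)


class TestFrameTransform:
    def test_identity_rotation_is_noop(self):
        trace = ModelerTrace(t=[0.0, 1.0], pos=[[1, 2, 3], [4, 5, 6]], frame="robot")
        out = to_patient_frame(trace, np.eye(3))
        np.testing.assert_array_equal(out.pos, trace.pos)
        np.testing.assert_array_equal(out.t, trace.t)
        assert out.frame == "patient"

    def test_quarter_turn_about_si_axis(self):
        # rotation about S-I maps the L-R displacement onto A-P
        rot = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        trace = ModelerTrace(t=[0.0], pos=[[0.0, 5.0, 0.0]], frame="robot")
        out = to_patient_frame(trace, rot)
        expected = rot @ np.array([0.0, 5.0, 0.0])
        np.testing.assert_allclose(out.pos[0], expected, atol=1e-12)
        np.testing.assert_allclose(out.pos[0], [0.0, 0.0, 5.0], atol=1e-12)

    def test_rotation_then_inverse_restores_trace(self, rng):
        angles = rng.uniform(0, 2 * np.pi, 3)
        from scipy.spatial.transform import Rotation

        r = Rotation.from_euler("xyz", angles).as_matrix()
        pos = rng.normal(0, 10, (50, 3))
        trace = ModelerTrace(t=np.arange(50.0), pos=pos, frame="robot")
        once = to_patient_frame(trace, r)
        back = to_patient_frame(
            ModelerTrace(t=once.t, pos=once.pos, frame="robot"), r.T
        )
        np.testing.assert_allclose(back.pos, pos, atol=1e-12)

    def test_matches_per_point_matrix_product(self, rng):
        from scipy.stats import ortho_group

        r = ortho_group.rvs(3, random_state=np.random.RandomState(7))
        pts = rng.normal(0, 5, (100, 3))
        fast = rotate_positions(pts, r)
        brute = np.array([r @ p for p in pts])
        np.testing.assert_allclose(fast, brute, atol=1e-12)

    def test_non_orthonormal_matrix_rejected(self):
        trace = ModelerTrace(t=[0.0], pos=[[1, 1, 1]], frame="robot")
        with pytest.raises(FrameError):
            to_patient_frame(trace, np.eye(3) * 1.001)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_transform_is_an_isometry(self, seed):
        from scipy.stats import ortho_group

        gen = np.random.RandomState(seed)
        r = ortho_group.rvs(3, random_state=gen)
        pts = gen.normal(0, 8, (20, 3))
        rotated = rotate_positions(pts, r)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(rotated[:, None] - rotated[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestBeamGating:
    def test_full_coverage_leaves_bundle_unchanged(self, quiet_fraction):
        _, bundle = quiet_fraction
        full = TrackingBundle(
            imaging=bundle.imaging,
            modeler=bundle.modeler,
            predictor=bundle.predictor,
            beam=BeamIntervals([[0.0, 1e6]]),
        )
        gated = gate_to_beam_on(full)
        assert bundles_equal(full, gated)
        assert not gated.excluded

    def test_empty_beam_flags_exclusion(self, quiet_fraction):
        _, bundle = quiet_fraction
        empty = TrackingBundle(
            imaging=bundle.imaging,
            modeler=bundle.modeler,
            predictor=bundle.predictor,
            beam=BeamIntervals(np.zeros((0, 2))),
        )
        gated = gate_to_beam_on(empty)
        assert gated.excluded
        assert len(gated.imaging) == 0 and len(gated.modeler) == 0

    def test_gating_is_idempotent(self, noisy_fraction):
        _, bundle = noisy_fraction
        once = gate_to_beam_on(bundle)
        twice = gate_to_beam_on(once)
        assert bundles_equal(once, twice)

    def test_retained_count_matches_brute_force_membership(self, noisy_fraction):
        _, bundle = noisy_fraction
        gated = gate_to_beam_on(bundle)
        for name in ("imaging", "modeler", "predictor"):
            t = getattr(bundle, name).t
            brute = sum(
                any(lo <= ti <= hi for lo, hi in bundle.beam.intervals) for ti in t
            )
            assert len(getattr(gated, name)) == brute

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            BeamIntervals([[0, 10], [5, 15]])


class TestStreamInvariants:
    def test_non_increasing_timestamps_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ImagingSeries(t=[0.0, 0.0], pos=np.zeros((2, 3)))

    def test_irregular_imaging_spacing_warns(self):
        with pytest.warns(UserWarning, match="spacing"):
            ImagingSeries(
                t=[0.0, 5.0, 10.0, 15.0], pos=np.zeros((4, 3)), nominal_interval_s=40.0
            )
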