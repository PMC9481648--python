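"""Marker preprocessing: filtering, segmentation, pose extraction, normalization."""

import io

import numpy as np
import pytest

from copair.markers import (
    MarkerSeries,
    lowpass_filter,
    normalize_time,
    pelvis_com_pose,
    read_markers_csv,
    segment_by_table_height,
    table_height_above_floor,
    table_pose,
)
from copair.trajectory import Trajectory

from conftest import make_traj

RATE = 200.0


def _series(xyz_per_marker, labels, rate=RATE):
    xyz = np.stack(xyz_per_marker, axis=1)
    t = np.arange(xyz.shape[0]) / rate
    return MarkerSeries(labels, t, xyz, rate)


def _sinusoid_series(freq, n=2000, amp=1.0):
    t = np.arange(n) / RATE
    sig = amp * np.sin(2 * np.pi * freq * t)
    xyz = np.zeros((n, 1, 3))
    xyz[:, 0, 0] = sig
    return MarkerSeries(["M"], t, xyz, RATE)


class TestLowpassFilter:
    def test_constant_signal_is_unchanged(self):
        xyz = np.full((500, 1, 3), 1.234)
        ser = MarkerSeries(["M"], np.arange(500) / RATE, xyz, RATE)
        out = lowpass_filter(ser, cutoff=10.0, order=4)
        assert np.allclose(out.xyz, 1.234, atol=1e-9)

    def test_passband_sinusoid_amplitude_preserved(self):
        # squared 4th-order Butterworth response at 1 Hz with 10 Hz cutoff: ~1
        out = lowpass_filter(_sinusoid_series(1.0), cutoff=10.0, order=4)
        mid = out.xyz[500:1500, 0, 0]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)

    def test_stopband_sinusoid_attenuated(self):
        # squared response at 50 Hz is ~(10/50)^8 << 1e-2
        out = lowpass_filter(_sinusoid_series(50.0), cutoff=10.0, order=4)
        mid = out.xyz[500:1500, 0, 0]
        assert np.max(np.abs(mid)) < 0.01

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(_sinusoid_series(1.0), cutoff=100.0, order=4)

    def test_odd_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            lowpass_filter(_sinusoid_series(1.0), cutoff=10.0, order=3)

    def test_short_gap_bridged_long_gap_names_marker(self):
        xyz = np.zeros((400, 1, 3))
        xyz[:, 0, 0] = np.linspace(0, 1, 400)
        xyz[100:105, 0, 0] = np.nan  # 5-sample gap: bridged
        ser = MarkerSeries(["PEL"], np.arange(400) / RATE, xyz, RATE)
        out = lowpass_filter(ser, 10.0, 4)
        assert np.all(np.isfinite(out.xyz))
        xyz[200:250, 0, 0] = np.nan  # 50-sample gap: fatal
        ser2 = MarkerSeries(["PEL"], np.arange(400) / RATE, xyz, RATE)
        with pytest.raises(ValueError, match="PEL"):
            lowpass_filter(ser2, 10.0, 4)


class TestSegmentation:
    def test_flat_floor_is_incomplete_trial(self):
        with pytest.raises(ValueError, match="incomplete trial"):
            segment_by_table_height(np.zeros(1000))

    def test_two_lift_segments_indexed_correctly(self):
        z = np.concatenate([np.zeros(100), np.full(200, 0.1), np.zeros(100),
                            np.full(200, 0.1), np.zeros(50)])
        segs = segment_by_table_height(z)
        assert segs.forward == (100, 300)
        assert segs.return_ == (400, 600)
        assert segs.approach == (0, 100)

    def test_default_threshold_is_5mm(self):
        z = np.concatenate([np.zeros(10), np.full(10, 0.004), np.zeros(10),
                            np.full(10, 0.006), np.zeros(10),
                            np.full(10, 0.006), np.zeros(10)])
        # the 4 mm bump is below the 5 mm default and must not count as a lift
        segs = segment_by_table_height(z)
        assert segs.forward == (30, 40)

    def test_extra_segments_reported(self):
        z = np.concatenate([np.zeros(10), np.ones(10), np.zeros(10), np.ones(10),
                            np.zeros(10), np.ones(10), np.zeros(10)])
        with pytest.raises(ValueError, match="candidate segments"):
            segment_by_table_height(z)

    def test_idempotent_on_own_window(self):
        z = np.concatenate([np.zeros(100), np.full(200, 0.1), np.zeros(100),
                            np.full(200, 0.1), np.zeros(50)])
        segs = segment_by_table_height(z)
        window = z[: segs.return_[1] + 10]
        assert segment_by_table_height(window).forward == segs.forward

    def test_floor_reference_uses_initial_rest(self):
        z = 0.37 + np.concatenate([np.zeros(200), np.full(100, 0.1), np.zeros(100),
                                   np.full(100, 0.1), np.zeros(100)])
        rez = table_height_above_floor(z, rate=RATE)
        assert rez[0] == pytest.approx(0.0)
        segs = segment_by_table_height(rez)
        assert segs.forward == (200, 300)


def _square_pelvis(theta=0.0, shift=(0.0, 0.0), n=5):
    """Unit-square pelvis markers, ASIS side facing +x when theta = 0."""
    corners = {
        "LASI": np.array([0.5, 0.5, 1.0]),
        "RASI": np.array([0.5, -0.5, 1.0]),
        "LPSI": np.array([-0.5, 0.5, 1.0]),
        "RPSI": np.array([-0.5, -0.5, 1.0]),
    }
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    labels = list(corners)
    xyz = np.stack(
        [np.tile(R @ corners[lb] + np.array([*shift, 0.0]), (n, 1)) for lb in labels],
        axis=1,
    )
    return MarkerSeries(labels, np.arange(n) / RATE, xyz, RATE)


class TestPelvisPose:
    def test_centered_square_gives_origin_pose(self):
        tr = pelvis_com_pose(_square_pelvis())
        assert np.allclose(tr.x, 0.0) and np.allclose(tr.y, 0.0)
        assert np.allclose(tr.theta, 0.0)

    def test_rotated_square(self):
        tr = pelvis_com_pose(_square_pelvis(theta=np.pi / 2))
        assert np.allclose(tr.x, 0.0, atol=1e-12) and np.allclose(tr.y, 0.0, atol=1e-12)
        assert np.allclose(tr.theta, np.pi / 2)

    def test_translation_moves_position_not_heading(self):
        tr = pelvis_com_pose(_square_pelvis(shift=(2.0, 3.0)))
        assert np.allclose(tr.x, 2.0) and np.allclose(tr.y, 3.0)
        assert np.allclose(tr.theta, 0.0)

    def test_missing_label_rejected(self):
        ser = _square_pelvis()
        ser.labels[0] = "WRONG"
        with pytest.raises(ValueError, match="missing pelvis markers"):
            pelvis_com_pose(ser)

    def test_degenerate_geometry_rejected(self):
        ser = _square_pelvis()
        ser.xyz[:] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            pelvis_com_pose(ser)


def _table_corners(theta=0.0, center=(0.0, 0.0), n=4):
    """Three consecutive corners of the 1.22 x 0.8 m top, long axis +x at theta = 0."""
    pts = [np.array([-0.61, 0.4, 0.77]), np.array([0.61, 0.4, 0.77]),
           np.array([0.61, -0.4, 0.77])]
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    xyz = np.stack(
        [np.tile(R @ p + np.array([*center, 0.0]), (n, 1)) for p in pts], axis=1
    )
    return MarkerSeries(["T1", "T2", "T3"], np.arange(n) / RATE, xyz, RATE)


class TestTablePose:
    def test_axis_aligned_rectangle(self):
        tr = table_pose(_table_corners())
        assert np.allclose([tr.x, tr.y, tr.theta], 0.0, atol=1e-12)

    def test_rotated_rectangle(self):
        tr = table_pose(_table_corners(theta=0.3))
        assert np.allclose(tr.theta, 0.3)
        assert np.allclose(tr.x, 0.0, atol=1e-12)

    def test_inconsistent_geometry_rejected(self):
        ser = _table_corners()
        ser.xyz[:, 1, 0] += 0.3  # stretch one edge by 30 cm
        with pytest.raises(ValueError, match="inconsistent"):
            table_pose(ser)


class TestNormalizeTime:
    def test_constant_trajectory_any_length(self):
        tr = make_traj(np.full(37, 2.0), np.full(37, -1.0), np.full(37, 0.3),
                       normalized=False)
        out = normalize_time(tr, 500)
        assert out.n == 500 and out.normalized
        assert np.allclose(out.x, 2.0) and np.allclose(out.theta, 0.3)

    def test_linear_ramp_is_exact(self):
        t = np.linspace(0.0, 1.0, 1000)
        tr = Trajectory("subject1", t, t, np.zeros(1000), np.zeros(1000))
        out = normalize_time(tr, 500)
        assert out.x[0] == 0.0 and out.x[-1] == 1.0
        assert np.allclose(out.x, np.linspace(0, 1, 500), atol=1e-12)

    def test_idempotent(self, ):
        rng = np.random.default_rng(3)
        tr = make_traj(np.cumsum(rng.normal(size=300)) * 0.01,
                       np.cumsum(rng.normal(size=300)) * 0.01,
                       np.cumsum(rng.normal(size=300)) * 0.001, normalized=False)
        once = normalize_time(tr, 500)
        twice = normalize_time(once, 500)
        assert np.allclose(once.x, twice.x, atol=1e-12)
        assert np.allclose(once.theta, twice.theta, atol=1e-12)

    def test_too_few_output_samples_rejected(self):
        tr = make_traj([0, 1], [0, 1], [0, 0.1], normalized=False)
        with pytest.raises(ValueError, match="n_out"):
            normalize_time(tr, 1)


@pytest.mark.parametrize("builder,extractor", [
    (_square_pelvis, pelvis_com_pose),
    (_table_corners, table_pose),
])
def test_pose_extraction_rigid_motion_equivariance(builder, extractor):
    """Rotating + translating all markers transforms the pose by the same motion."""
    rng = np.random.default_rng(42)
    base = extractor(builder())
    for _ in range(100):
        ang = rng.uniform(-np.pi, np.pi)
        shift = rng.uniform(-5, 5, size=2)
        moved = extractor(builder(theta=ang, center=shift) if builder is _table_corners
                          else builder(theta=ang, shift=shift))
        c, s = np.cos(ang), np.sin(ang)
        expect_xy = np.stack([c * base.x - s * base.y + shift[0],
                              s * base.x + c * base.y + shift[1]])
        assert np.allclose(moved.x, expect_xy[0], atol=1e-9)
        assert np.allclose(moved.y, expect_xy[1], atol=1e-9)
        d = (moved.theta - base.theta - ang + np.pi) % (2 * np.pi) - np.pi
        assert np.allclose(d, 0.0, atol=1e-9)


def test_read_markers_csv_roundtrip(tmp_path):
    t = np.arange(20) / RATE
    df_cols = {"time": t}
    for lb in ("A", "B"):
        for ax, val in zip("xyz", (1.0, 2.0, 3.0)):
            df_cols[f"{lb}_{ax}"] = np.full(20, val)
    import pandas as pd

    path = tmp_path / "m.csv"
    pd.DataFrame(df_cols).to_csv(path, index=False)
    ser = read_markers_csv(path)
    assert ser.labels == ["A", "B"]
    assert ser.rate == pytest.approx(RATE)
    assert np.allclose(ser.marker("B"), [1.0, 2.0, 3.0])
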