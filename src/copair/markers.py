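"""Motion-capture marker preprocessing.

Raw input is a set of 3-D marker time series (nominally 200 Hz): four
pelvis markers per subject (LASI, RASI, LPSI, RPSI) and three table-corner
markers.  The pipeline is the standard gait-lab sequence:

1. zero-phase low-pass Butterworth filtering (default 4th order, 10 Hz);
2. trial segmentation from the table height — a carriage segment runs from
   the sample where the table rises above 5 mm off the floor to the sample
   where it returns below; a complete trial has exactly two such segments
   (forward path, return path);
3. reduction of markers to planar poses: pelvis centroid + anatomical
   heading for the subjects, rectangle centre + long-axis heading for the
   table;
4. time normalization of each segment to 0–100 % on 500 samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from ._angles import unwrap
from .trajectory import Trajectory

PELVIS_LABELS = ("LASI", "RASI", "LPSI", "RPSI")
TABLE_LENGTH = 1.22  # m, long side of the table top
TABLE_WIDTH = 0.80  # m, short side
LIFT_THRESHOLD = 0.005  # m, table height marking carriage on/offset
MAX_GAP_SAMPLES = 10  # longest NaN run we interpolate over

__all__ = [
    "MarkerSeries",
    "TrialSegments",
    "read_markers_csv",
    "lowpass_filter",
    "segment_by_table_height",
    "pelvis_com_pose",
    "table_pose",
    "normalize_time",
    "table_height_above_floor",
]


@dataclass
class MarkerSeries:
    """Uniformly sampled 3-D positions for a set of labelled markers.

    ``xyz`` has shape (n_samples, n_markers, 3), metres.  Gaps are flagged
    as NaN, never silently dropped.
    """

    labels: list
    t: np.ndarray
    xyz: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_samples, n_markers, 3)")
        if self.xyz.shape[0] != self.t.size:
            raise ValueError("time and marker arrays disagree in length")
        if self.xyz.shape[1] != len(self.labels):
            raise ValueError("labels and marker arrays disagree in count")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.t.size)

    def marker(self, label: str) -> np.ndarray:
        """(n, 3) positions of one marker."""
        try:
            j = self.labels.index(label)
        except ValueError as exc:
            raise KeyError(f"marker {label!r} not present (have {self.labels})") from exc
        return self.xyz[:, j, :]

    def subset(self, labels: Sequence[str]) -> "MarkerSeries":
        idx = [self.labels.index(lb) for lb in labels]
        return MarkerSeries(list(labels), self.t, self.xyz[:, idx, :], self.rate)

    def window(self, start: int, stop: int) -> "MarkerSeries":
        return MarkerSeries(self.labels, self.t[start:stop], self.xyz[start:stop], self.rate)


@dataclass(frozen=True)
class TrialSegments:
    """Index windows of one trial: approach, forward carriage, return carriage."""

    forward: tuple
    return_: tuple
    approach: tuple

    def __post_init__(self) -> None:
        for a, b in (self.forward, self.return_):
            if not a < b:
                raise ValueError("segment onset must precede offset")
        if self.forward[1] > self.return_[0]:
            raise ValueError("forward offset must not exceed return onset")


def read_markers_csv(path) -> MarkerSeries:
    """Read a marker CSV: columns ``time, <marker>_x, <marker>_y, <marker>_z`` (m)."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError("marker CSV must have a 'time' column")
    t = df["time"].to_numpy(float)
    labels = []
    for col in df.columns:
        if col.endswith("_x"):
            lb = col[:-2]
            if f"{lb}_y" in df.columns and f"{lb}_z" in df.columns:
                labels.append(lb)
    if not labels:
        raise ValueError("no '<marker>_x/_y/_z' column triplets found")
    xyz = np.stack(
        [np.column_stack([df[f"{lb}_{ax}"].to_numpy(float) for ax in "xyz"]) for lb in labels],
        axis=1,
    )
    dt = np.diff(t)
    rate = 1.0 / float(np.median(dt))
    return MarkerSeries(labels, t, xyz, rate)


def _fill_short_gaps(x: np.ndarray, t: np.ndarray, label: str, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; longer runs are an error."""
    x = x.copy()
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad[0] or bad[-1]:
        raise ValueError(f"marker {label!r} has a gap at the series boundary")
    # run-length encode the NaN mask
    edges = np.flatnonzero(np.diff(bad.astype(int)))
    starts = edges[::2] + 1
    stops = edges[1::2] + 1
    for a, b in zip(starts, stops):
        if b - a > max_gap:
            raise ValueError(
                f"marker {label!r} has a {b - a}-sample gap (> {max_gap}); trial unusable"
            )
    good = ~bad
    x[bad] = np.interp(t[bad], t[good], x[good])
    return x


def lowpass_filter(series: MarkerSeries, cutoff: float = 10.0, order: int = 4) -> MarkerSeries:
    """Zero-phase low-pass Butterworth filter, applied per marker coordinate.

    The filter of the requested design ``order`` is run forward and
    backward (``filtfilt``), giving zero phase shift and the squared
    magnitude response of the design.  NaN gaps up to 10 samples are
    bridged by linear interpolation first; longer gaps raise, naming the
    marker, rather than silently imputing.
    """
    if order <= 0 or order % 2:
        raise ValueError("filter order must be a positive even integer")
    nyquist = series.rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist rate {nyquist} Hz")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(order, cutoff, btype="low", fs=series.rate, output="sos")
    out = np.empty_like(series.xyz)
    for j, label in enumerate(series.labels):
        for ax in range(3):
            x = _fill_short_gaps(series.xyz[:, j, ax], series.t, label, MAX_GAP_SAMPLES)
            out[:, j, ax] = signal.sosfiltfilt(sos, x)
    return MarkerSeries(series.labels, series.t.copy(), out, series.rate)


def table_height_above_floor(table_z: np.ndarray, rate: float, settle: float = 0.5) -> np.ndarray:
    """Re-reference a table height signal to the floor.

    The floor level is taken as the minimum over the first ``settle``
    seconds of the trial, when the table is still resting on the ground.
    """
    z = np.asarray(table_z, dtype=float)
    k = max(1, int(round(settle * rate)))
    return z - np.nanmin(z[:k])


def segment_by_table_height(table_z: np.ndarray, threshold: float = LIFT_THRESHOLD) -> TrialSegments:
    """Segment a trial from the table height relative to the floor.

    A carriage segment starts at the first sample where the height exceeds
    ``threshold`` (default 5 mm) and ends at the first subsequent sample
    at or below it.  A complete trial has exactly two segments: forward
    path then return path.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(table_z, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("table height contains non-finite samples")
    up = z > threshold
    segments = []
    i = 0
    n = z.size
    while i < n:
        if up[i]:
            j = i
            while j < n and up[j]:
                j += 1
            if j < n:  # only closed segments (table set back down) count
                segments.append((i, j))
            i = j
        else:
            i += 1
    if len(segments) < 2:
        raise ValueError("incomplete trial: fewer than two table-lift segments found")
    if len(segments) > 2:
        raise ValueError(
            "more than two table-lift segments found; candidate segments: "
            f"{segments} (merge or re-threshold upstream)"
        )
    (f0, f1), (r0, r1) = segments
    return TrialSegments(forward=(f0, f1), return_=(r0, r1), approach=(0, f0))


def pelvis_com_pose(pelvis_markers: MarkerSeries, entity: str = "subject1") -> Trajectory:
    """Planar CoM pose of a subject from the four pelvis markers.

    Position is the horizontal centroid of LASI, RASI, LPSI, RPSI; heading
    is the direction of the vector from the PSIS midpoint to the ASIS
    midpoint (anterior axis of the pelvic anatomical frame), unwrapped.
    """
    missing = [lb for lb in PELVIS_LABELS if lb not in pelvis_markers.labels]
    if missing:
        raise ValueError(f"missing pelvis markers: {missing}")
    lasi = pelvis_markers.marker("LASI")
    rasi = pelvis_markers.marker("RASI")
    lpsi = pelvis_markers.marker("LPSI")
    rpsi = pelvis_markers.marker("RPSI")
    centroid = (lasi + rasi + lpsi + rpsi) / 4.0
    asis_mid = 0.5 * (lasi + rasi)
    psis_mid = 0.5 * (lpsi + rpsi)
    anterior = asis_mid[:, :2] - psis_mid[:, :2]
    norms = np.hypot(anterior[:, 0], anterior[:, 1])
    if np.any(norms < 1e-9):
        raise ValueError("degenerate pelvis geometry: ASIS and PSIS midpoints coincide")
    theta = unwrap(np.arctan2(anterior[:, 1], anterior[:, 0]))
    return Trajectory(entity, pelvis_markers.t, centroid[:, 0], centroid[:, 1], theta)


def table_pose(
    corner_markers: MarkerSeries,
    length: float = TABLE_LENGTH,
    width: float = TABLE_WIDTH,
    tol: float = 0.05,
) -> Trajectory:
    """Planar pose of the table from three corner markers.

    The three markers are consecutive corners of the 1.22 x 0.8 m top; the
    fourth corner is reconstructed by the parallelogram rule
    (P4 = P1 + P3 - P2).  Position is the centre of the four corners;
    heading is the direction of the long edge, unwrapped.  Edge lengths
    inconsistent with the table dimensions beyond ``tol`` raise.
    """
    if len(corner_markers.labels) != 3:
        raise ValueError("table pose needs exactly 3 corner markers")
    p1, p2, p3 = (corner_markers.xyz[:, j, :] for j in range(3))
    e12 = np.linalg.norm((p2 - p1)[:, :2], axis=1)
    e23 = np.linalg.norm((p3 - p2)[:, :2], axis=1)
    lengths = np.stack([np.median(e12), np.median(e23)])
    expect = np.array(sorted([length, width]))
    if np.any(np.abs(np.sort(lengths) - expect) > tol):
        raise ValueError(
            f"inter-marker distances {lengths.tolist()} m inconsistent with the "
            f"{length} x {width} m table top (tolerance {tol} m)"
        )
    p4 = p1 + p3 - p2
    center = 0.25 * (p1 + p2 + p3 + p4)
    long_edge = (p2 - p1) if lengths[0] >= lengths[1] else (p3 - p2)
    theta = unwrap(np.arctan2(long_edge[:, 1], long_edge[:, 0]))
    return Trajectory("table", corner_markers.t, center[:, 0], center[:, 1], theta)


def normalize_time(traj: Trajectory, n_out: int = 500) -> Trajectory:
    """Resample a trajectory onto ``n_out`` samples of normalized time 0–100 %.

    Linear interpolation per coordinate; theta is interpolated on the
    unwrapped signal; the first and last poses are preserved exactly.
    """
    if n_out < 2:
        raise ValueError("n_out must be at least 2")
    s_in = (traj.t - traj.t[0]) / (traj.t[-1] - traj.t[0]) * 100.0
    s_out = np.linspace(0.0, 100.0, n_out)
    x = np.interp(s_out, s_in, traj.x)
    y = np.interp(s_out, s_in, traj.y)
    theta = np.interp(s_out, s_in, traj.theta)
    x[0], y[0], theta[0] = traj.x[0], traj.y[0], traj.theta[0]
    x[-1], y[-1], theta[-1] = traj.x[-1], traj.y[-1], traj.theta[-1]
    return Trajectory(traj.entity, s_out, x, y, theta, normalized=True)
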