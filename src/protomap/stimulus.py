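"""Synthetic moving-bar event streams in address-event representation (AER).

A dynamic vision sensor (DVS) "silicon retina" reports asynchronous per-pixel
brightness changes as timestamped events instead of frames.  A bright bar
sweeping over a dark background produces ON events (+1 polarity) along its
leading edge.  This module synthesises such streams on a 128x128 sensor for a
bar moving in one of the eight compass directions, and serialises them to a
simple binary AER container (4-byte address + 4-byte timestamp records).

Event emission is Poisson per leading-edge pixel while the edge crosses that
pixel, which mimics the stochastic firing of real DVS pixels; a deterministic
mode (exactly one event per pixel crossing) is available for exact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SENSOR_SHAPE",
    "COMPASS_ANGLES_DEG",
    "EventStream",
    "BarStimulusSpec",
    "generate_bar_events",
    "write_aer",
    "read_aer",
]

SENSOR_SHAPE = (128, 128)

#: Compass token -> motion angle, mathematical convention on the image plane:
#: E = 0 deg (increasing x), N = 90 deg (increasing y), angles anticlockwise.
COMPASS_ANGLES_DEG = {
    "E": 0.0,
    "NE": 45.0,
    "N": 90.0,
    "NW": 135.0,
    "W": 180.0,
    "SW": 225.0,
    "S": 270.0,
    "SE": 315.0,
}


class AERFormatError(ValueError):
    """Raised when a binary AER file cannot be decoded."""


@dataclass
class EventStream:
    """Timestamped ON/OFF events on a fixed-size sensor grid.

    Attributes
    ----------
    x, y : int arrays, pixel coordinates in [0, 127].
    polarity : int array, +1 (ON) or -1 (OFF).
    t : int array, microsecond timestamps, sorted non-decreasing.
    """

    x: np.ndarray
    y: np.ndarray
    polarity: np.ndarray
    t: np.ndarray
    sensor_shape: tuple[int, int] = SENSOR_SHAPE

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.polarity = np.asarray(self.polarity, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.int64)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.polarity) == n):
            raise ValueError("event field arrays must have equal length")
        h, w = self.sensor_shape
        if n:
            if self.x.min() < 0 or self.x.max() >= w:
                raise ValueError("x coordinates outside sensor bounds")
            if self.y.min() < 0 or self.y.max() >= h:
                raise ValueError("y coordinates outside sensor bounds")
            if not np.isin(self.polarity, (-1, 1)).all():
                raise ValueError("polarity must be +1 or -1")
            if self.t.min() < 0:
                raise ValueError("timestamps must be non-negative")
            if np.any(np.diff(self.t) < 0):
                raise ValueError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.sensor_shape == other.sensor_shape
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.polarity, other.polarity)
            and np.array_equal(self.t, other.t)
        )

    @property
    def duration_s(self) -> float:
        """Time of the last event, in seconds (0 for an empty stream)."""
        return float(self.t[-1]) * 1e-6 if len(self) else 0.0


@dataclass
class BarStimulusSpec:
    """Geometry and statistics of one moving-bar presentation.

    The bar is a rectangle of ``bar_width_px`` along the motion axis and
    ``bar_length_px`` across it, translating at ``speed_px_per_s`` in the
    given compass ``direction``.  ON events are emitted from the leading
    edge only.  ``duration_s`` defaults to the full traversal time of the
    field.  ``lateral_offset_px`` shifts the bar perpendicular to its
    motion, which is how distinct stimulus instances differ.
    """

    direction: str = "E"
    bar_width_px: int = 8
    bar_length_px: int = 128
    speed_px_per_s: float = 128.0
    duration_s: float | None = None
    event_rate_per_edge_pixel: float = 200.0
    lateral_offset_px: float = 0.0
    deterministic: bool = False
    seed: int = 0
    sensor_shape: tuple[int, int] = SENSOR_SHAPE

    def __post_init__(self) -> None:
        if self.direction not in COMPASS_ANGLES_DEG:
            raise ValueError(
                f"unknown direction {self.direction!r}; "
                f"expected one of {sorted(COMPASS_ANGLES_DEG)}"
            )
        if self.speed_px_per_s <= 0:
            raise ValueError("speed_px_per_s must be positive")
        if self.event_rate_per_edge_pixel < 0:
            raise ValueError("event_rate_per_edge_pixel must be >= 0")
        if self.bar_width_px <= 0 or self.bar_length_px <= 0:
            raise ValueError("bar dimensions must be positive")
        if self.duration_s is None:
            self.duration_s = self.traversal_time_s
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def angle_deg(self) -> float:
        return COMPASS_ANGLES_DEG[self.direction]

    @property
    def traversal_time_s(self) -> float:
        """Time for the leading edge to cross the whole field."""
        h, w = self.sensor_shape
        th = math.radians(self.angle_deg)
        # Extent of the field projected onto the motion axis, plus one pixel
        # so the edge fully clears the last pixel.
        extent = abs((w - 1) * math.cos(th)) + abs((h - 1) * math.sin(th)) + 1.0
        return extent / self.speed_px_per_s


def generate_bar_events(spec: BarStimulusSpec) -> EventStream:
    """Simulate the ON-event stream of a bar sweeping the sensor.

    For every pixel the leading edge passes over, the time window during
    which the edge covers that pixel is computed from the pixel centre's
    projection onto the motion axis.  Events within the window are Poisson
    with rate ``spec.event_rate_per_edge_pixel`` (or exactly one event at
    the window midpoint in deterministic mode).  The same seed always
    yields the identical stream; simultaneous events are ordered by (y, x).
    """
    h, w = spec.sensor_shape
    th = math.radians(spec.angle_deg)
    ux, uy = math.cos(th), math.sin(th)

    xs, ys = np.meshgrid(np.arange(w), np.arange(h), indexing="xy")
    xs = xs.ravel().astype(np.float64)
    ys = ys.ravel().astype(np.float64)

    proj = xs * ux + ys * uy          # along-motion coordinate of each pixel
    perp = -xs * uy + ys * ux         # across-motion coordinate

    # Bar occupies a band of width bar_length_px across the motion axis,
    # centred on the field centre plus the per-instance lateral offset.
    c = (-(w - 1) * uy + (h - 1) * ux) / 2.0 + spec.lateral_offset_px
    in_band = np.abs(perp - c) <= spec.bar_length_px / 2.0

    # Leading edge enters the field at t=0 and advances at constant speed.
    start = proj.min() - 0.5
    v = spec.speed_px_per_s
    t_enter = (proj - 0.5 - start) / v
    t_exit = (proj + 0.5 - start) / v

    valid = in_band & (t_enter < spec.duration_s)
    xs, ys = xs[valid], ys[valid]
    t_enter, t_exit = t_enter[valid], np.minimum(t_exit[valid], spec.duration_s)
    window = t_exit - t_enter

    if spec.deterministic:
        counts = np.ones(len(xs), dtype=np.int64)
        times = (t_enter + window / 2.0)
        ex, ey, et = xs, ys, times
    else:
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(spec.event_rate_per_edge_pixel * window)
        ex = np.repeat(xs, counts)
        ey = np.repeat(ys, counts)
        et = np.repeat(t_enter, counts) + rng.random(counts.sum()) * np.repeat(
            window, counts
        )

    t_us = np.round(et * 1e6).astype(np.int64)
    order = np.lexsort((ex, ey, t_us))
    return EventStream(
        x=ex[order].astype(np.int64),
        y=ey[order].astype(np.int64),
        polarity=np.ones(len(order), dtype=np.int64),
        t=t_us[order],
        sensor_shape=spec.sensor_shape,
    )


def instance_spec(spec: BarStimulusSpec, instance: int, seed: int) -> BarStimulusSpec:
    """Derive the spec for one stimulus instance: new Poisson seed and a
    small lateral offset so repeated presentations are not identical."""
    offsets = (0.0, 1.5, -1.5, 3.0, -3.0, 4.5, -4.5, 6.0, -6.0, 7.5)
    off = offsets[instance % len(offsets)] + 8.0 * (instance // len(offsets))
    return replace(spec, seed=seed, lateral_offset_px=spec.lateral_offset_px + off)


# --- binary AER serialisation -------------------------------------------------
#
# Fixed 8-byte records: uint32 big-endian address, uint32 big-endian timestamp
# in microseconds.  Address bit layout: bit 0 = polarity (1 = ON), bits 1-8 = x,
# bits 9-16 = y, higher bits zero.  This is this package's own layout; it makes
# no attempt to match any .aedat dialect.

_RECORD_DTYPE = np.dtype([("address", ">u4"), ("timestamp", ">u4")])


def write_aer(stream: EventStream, path) -> None:
    """Serialise a stream as fixed 8-byte big-endian AER records."""
    pol_bit = (stream.polarity == 1).astype(np.uint32)
    address = pol_bit | (stream.x.astype(np.uint32) << 1) | (
        stream.y.astype(np.uint32) << 9
    )
    rec = np.empty(len(stream), dtype=_RECORD_DTYPE)
    rec["address"] = address
    rec["timestamp"] = stream.t.astype(np.uint32)
    with open(path, "wb") as fh:
        fh.write(rec.tobytes())


def read_aer(path) -> EventStream:
    """Decode a binary AER file written by :func:`write_aer`."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) % 8:
        raise AERFormatError(
            f"file length {len(raw)} is not a multiple of the 8-byte record size"
        )
    rec = np.frombuffer(raw, dtype=_RECORD_DTYPE)
    address = rec["address"].astype(np.uint32)
    x = ((address >> 1) & 0xFF).astype(np.int64)
    y = ((address >> 9) & 0xFF).astype(np.int64)
    polarity = np.where((address & 1) == 1, 1, -1).astype(np.int64)
    t = rec["timestamp"].astype(np.int64)
    h, w = SENSOR_SHAPE
    if len(x) and (x.max() >= w or y.max() >= h):
        raise AERFormatError("decoded coordinates outside the 128x128 sensor")
    if (address >> 17).any():
        raise AERFormatError("reserved address bits are set")
    order = np.lexsort((x, y, t))
    return EventStream(x=x[order], y=y[order], polarity=polarity[order], t=t[order])
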