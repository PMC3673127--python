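"""Simulated pen / LED / color-sensor chain.

The physical chain illuminates a small spot on the map through an optical
fiber and routes the scattered light to an RGB color sensor; raw channel
counts arrive at ~30 samples/s.  The simulator reproduces the artifact
classes that matter to the decoding algorithm:

* spot averaging — the sensor sees the mean color over an illuminated disc;
* per-channel gains (counts per byte level of reflectance);
* a slow shared luminance drift (fiber bending, supply variation, map wear),
  modeled as a log-luminance random walk;
* per-sample multiplicative channel noise;
* an abrupt multiplicative count collapse when the pen leaves the surface,
  fast enough to satisfy the >50%-in-<250 ms lift-off detection premise.

Multiplicative forms are deliberate: they are exactly what downstream
sum-normalization is designed to cancel.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .colormap import ColorMapSpec, ideal_color_float, in_usable_span, spec_hash


@dataclass(frozen=True)
class SensorModel:
    """Gains, optics and noise of the simulated sensor chain."""

    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    spot_radius_mm: float = 1.0
    rel_noise_sigma: float = 0.02
    luminance_walk_sigma: float = 0.002
    sample_rate_hz: float = 30.0
    liftoff_floor: float = 0.05

    def __post_init__(self) -> None:
        if min(self.gain) <= 0 or self.spot_radius_mm <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("gains, spot radius and sample rate must be positive")
        if self.rel_noise_sigma < 0 or self.luminance_walk_sigma < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not (0 < self.liftoff_floor < 0.5):
            raise ValueError("liftoff_floor must be in (0, 0.5)")


@dataclass(frozen=True)
class PenPose:
    position: tuple[float, float]
    in_contact: bool = True


def _hex_disc_points(radius: float) -> np.ndarray:
    # Hexagonal lattice patch of "radius" 3 rings: 1 + 6 + 12 + 18 = 37 points.
    # Centro-symmetric, so the unweighted mean is exact for affine fields.
    s = radius / 3.0
    a1 = np.array([s, 0.0])
    a2 = np.array([s * 0.5, s * np.sqrt(3.0) / 2.0])
    pts = []
    for i in range(-3, 4):
        for j in range(-3, 4):
            if max(abs(i), abs(j), abs(i + j)) <= 3:
                pts.append(i * a1 + j * a2)
    out = np.array(pts)
    assert out.shape == (37, 2)
    return out


_DISC_CACHE: dict[float, np.ndarray] = {}


def spot_mean_color(
    spec: ColorMapSpec, model: SensorModel, position) -> np.ndarray:
    """Mean ideal RGB over the illuminated disc (37-point hex quadrature)."""
    r = model.spot_radius_mm
    if r not in _DISC_CACHE:
        _DISC_CACHE[r] = _hex_disc_points(r)
    pts = np.asarray(position, dtype=float) + _DISC_CACHE[r]
    return ideal_color_float(spec, pts).mean(axis=0)


def read_counts(
    spec: ColorMapSpec,
    model: SensorModel,
    pose: PenPose,
    rng: np.random.Generator | None = None,
    luminance: float = 1.0,
) -> np.ndarray:
    """One raw (R, G, B) count triple for the given pen pose.

    counts = gain * disc-mean reflectance * luminance * (1 + noise), further
    multiplied by ``liftoff_floor`` when the pen is not in contact.
    """
    base = spot_mean_color(spec, model, pose.position)
    counts = base * np.asarray(model.gain) * luminance
    if model.rel_noise_sigma > 0 and rng is not None:
        counts = counts * (1.0 + rng.normal(0.0, model.rel_noise_sigma, size=3))
    if not pose.in_contact:
        counts = counts * model.liftoff_floor
    return np.clip(counts, 0.0, None)


# -- trajectory scripts ------------------------------------------------------

@dataclass(frozen=True)
class PathSegment:
    """Pen-down traversal through waypoints at constant speed along arc length."""

    waypoints: tuple[tuple[float, float], ...]
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if len(self.waypoints) < 1:
            raise ValueError("need at least one waypoint")

    def position_at(self, frac: float) -> np.ndarray:
        wp = np.asarray(self.waypoints, dtype=float)
        if len(wp) == 1:
            return wp[0]
        seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        if total == 0.0:
            return wp[0]
        s = np.clip(frac, 0.0, 1.0) * total
        k = int(np.searchsorted(cum, s, side="right") - 1)
        k = min(k, len(seg) - 1)
        t = (s - cum[k]) / seg[k] if seg[k] > 0 else 0.0
        return wp[k] + t * (wp[k + 1] - wp[k])


@dataclass(frozen=True)
class PenUpSegment:
    """Pen lifted (hovering over its last position) for a fixed dwell."""

    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class TrajectoryScript:
    segments: tuple

    def __post_init__(self) -> None:
        for s in self.segments:
            if not isinstance(s, (PathSegment, PenUpSegment)):
                raise TypeError(f"bad segment {s!r}")

    @property
    def duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def validate_span(self, spec: ColorMapSpec) -> None:
        for s in self.segments:
            if isinstance(s, PathSegment):
                wp = np.asarray(s.waypoints, dtype=float)
                if not np.all(in_usable_span(spec, wp)):
                    raise ValueError("script waypoint outside the usable span")

    def pose_at(self, t: float) -> PenPose:
        """Pen pose at absolute time t (pen-up segments hover in place)."""
        t0 = 0.0
        last_pos = None
        for s in self.segments:
            t1 = t0 + s.duration_s
            if t < t1 or s is self.segments[-1]:
                if isinstance(s, PathSegment):
                    frac = (t - t0) / s.duration_s
                    return PenPose(tuple(s.position_at(frac)), in_contact=True)
                pos = last_pos if last_pos is not None else self._first_down_pos()
                return PenPose(tuple(pos), in_contact=False)
            if isinstance(s, PathSegment):
                last_pos = s.position_at(1.0)
            t0 = t1
        raise ValueError("empty script")

    def _first_down_pos(self) -> np.ndarray:
        for s in self.segments:
            if isinstance(s, PathSegment):
                return np.asarray(s.waypoints[0], dtype=float)
        return np.array([0.0, 0.0])


@dataclass
class SampleStream:
    """Time-stamped raw channel counts, plus reproducibility metadata."""

    t: np.ndarray          # (n,) seconds, strictly increasing
    counts: np.ndarray     # (n, 3) raw non-negative counts
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def scaled(self, k: float) -> "SampleStream":
        """Stream with every raw count multiplied by k (luminance change)."""
        return SampleStream(self.t.copy(), self.counts * k, dict(self.meta))


def simulate_stream(
    spec: ColorMapSpec,
    model: SensorModel,
    script: TrajectoryScript,
    seed: int = 0,
) -> SampleStream:
    """Clock the script at ``model.sample_rate_hz`` through the sensor chain.

    Deterministic given the seed: one generator drives, per sample, first the
    luminance-walk increment, then the three channel-noise draws.
    """
    if not script.segments:
        return SampleStream(np.empty(0), np.empty((0, 3)),
                            {"spec_hash": spec_hash(spec), "seed": seed})
    script.validate_span(spec)
    rng = np.random.default_rng(seed)
    rate = model.sample_rate_hz
    n = int(np.floor(script.duration_s * rate + 1e-9))
    t = np.arange(n) / rate
    counts = np.empty((n, 3))
    log_lum = 0.0
    for k in range(n):
        if model.luminance_walk_sigma > 0:
            log_lum += rng.normal(0.0, model.luminance_walk_sigma)
        pose = script.pose_at(t[k])
        counts[k] = read_counts(
            spec, model, pose,
            rng=rng if model.rel_noise_sigma > 0 else None,
            luminance=float(np.exp(log_lum)),
        )
    return SampleStream(t, counts, {
        "spec_hash": spec_hash(spec),
        "seed": seed,
        "sample_rate_hz": rate,
    })


def stationary_sampler(
    spec: ColorMapSpec, model: SensorModel, seed: int = 0):
    """Sampler(position, n) -> (n, 3) counts for a held, in-contact pen.

    This is the simulator's stand-in for the guided-calibration prompt loop:
    the operator holds the pen at a marked grid point while n samples accrue.
    One generator persists across calls so repeated prompts share the same
    luminance-drift history.
    """
    rng = np.random.default_rng(seed)
    log_lum = 0.0

    def sample(position, n_samples: int) -> np.ndarray:
        nonlocal log_lum
        out = np.empty((n_samples, 3))
        pose = PenPose(tuple(np.asarray(position, dtype=float)))
        for k in range(n_samples):
            if model.luminance_walk_sigma > 0:
                log_lum += rng.normal(0.0, model.luminance_walk_sigma)
            out[k] = read_counts(
                spec, model, pose,
                rng=rng if model.rel_noise_sigma > 0 else None,
                luminance=float(np.exp(log_lum)),
            )
        return out

    return sample


# -- sensor-log format -------------------------------------------------------

def write_sensor_log(stream: SampleStream, path) -> None:
    """TSV: '#' metadata lines, header, then t_s / r / g / b counts."""
    buf = io.StringIO()
    for key, val in sorted(stream.meta.items()):
        buf.write(f"# {key}={val}\n")
    buf.write("t_s\tr_counts\tg_counts\tb_counts\n")
    for t, (r, g, b) in zip(stream.t, stream.counts):
        buf.write(f"{t:.6f}\t{r:.6f}\t{g:.6f}\t{b:.6f}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_sensor_log(path) -> SampleStream:
    meta: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("t_s"):
                continue
            rows.append([float(v) for v in line.split("\t")])
    arr = np.asarray(rows, dtype=float).reshape(-1, 4)
    return SampleStream(arr[:, 0], arr[:, 1:4], meta)
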