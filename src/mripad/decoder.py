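"""Stream decoding: lift-off detection, strokes, metrics, precision test.

Raw count triples become positions through sum-normalization and the inverse
LUT.  Two redundant cues segment the stream into strokes: a sudden summed-
count collapse (>50% within <250 ms by default) and an off-map color read.
A pen-up dwell longer than a configured period completes a response —
mirroring the acquisition protocol in which response completion advanced
the trial sequence.

Because absolute luminance carries no position information (and the
simulated count collapse is purely multiplicative, preserving chromaticity),
contact state must be tracked relative to recent in-contact levels; every
rule here is a ratio of summed counts, which keeps the whole decoder exactly
invariant to global count rescaling.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .lut import InverseLUT
from .sensor import SampleStream, SensorModel, PathSegment, TrajectoryScript, simulate_stream


@dataclass(frozen=True)
class LiftoffConfig:
    drop_fraction: float = 0.5
    drop_window_s: float = 0.25
    completion_dwell_s: float = 1.0
    require_offmap_confirmation: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.drop_fraction < 1):
            raise ValueError("drop_fraction must be in (0, 1)")
        if self.drop_window_s <= 0 or self.completion_dwell_s <= 0:
            raise ValueError("windows must be positive")


@dataclass
class Stroke:
    """Samples between one pen-down and the next lift-off."""

    t: np.ndarray            # (k,) seconds
    pixels: np.ndarray       # (k, 2) int (ix, iy)
    mm: np.ndarray           # (k, 2) causally smoothed positions, frame mm

    def __post_init__(self) -> None:
        if len(self.t) < 1:
            raise ValueError("a stroke needs at least one point")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("stroke timestamps must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def path_length_mm(self) -> float:
        if len(self.mm) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.mm, axis=0), axis=1).sum())


@dataclass
class HesitationEvent:
    t_start_s: float
    duration_s: float


@dataclass
class StrokeMetrics:
    stroke_count: int
    path_lengths_mm: list
    mean_speeds_mm_s: list
    peak_speeds_mm_s: list
    hesitations: list
    liftoff_count: int
    pen_down_time_s: float


@dataclass
class ResponseRecord:
    strokes: list
    completed_at: float
    metrics: StrokeMetrics | None = None


@dataclass
class DecodeResult:
    responses: list
    sample_table: np.ndarray   # (n, 6): t, pen_down, stroke_id, response_id, x, y
    events: list               # (completed_at, response_id) trial-advance events
    per_sample_seconds: float  # measured processing budget per sample
    meta: dict = field(default_factory=dict)


def detect_liftoff(t: np.ndarray, summed_counts: np.ndarray,
                   cfg: LiftoffConfig = LiftoffConfig(),
                   offmap_flags: np.ndarray | None = None) -> bool:
    """True iff the window contains a lift-off signature.

    The drop rule fires when the summed counts fall by more than
    ``drop_fraction`` of a sub-interval's starting value within any
    sub-interval no longer than ``drop_window_s``.  When
    ``require_offmap_confirmation`` is set, an off-map color read anywhere in
    the window raises the flag through the redundant color channel.
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(summed_counts, dtype=float)
    for j in range(len(s)):
        for i in range(j):
            if t[j] - t[i] <= cfg.drop_window_s and s[j] < (1 - cfg.drop_fraction) * s[i]:
                return True
    if cfg.require_offmap_confirmation and offmap_flags is not None:
        if np.any(offmap_flags):
            return True
    return False


def smooth_positions(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Causal rolling mean over the last ``min(window, available)`` points.

    Real-time constraint: only past samples enter the average, so the
    smoothed trace lags by about (window - 1) / 2 samples.  Callers reset
    the window at stroke boundaries (no smoothing across lift-offs).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    p = np.asarray(points, dtype=float)
    if p.ndim == 1:
        return smooth_positions(p[:, None], window)[:, 0]
    out = np.empty_like(p)
    csum = np.cumsum(p, axis=0)
    n = len(p)
    for k in range(n):
        lo = max(0, k - window + 1)
        tot = csum[k] - (csum[lo - 1] if lo > 0 else 0.0)
        out[k] = tot / (k - lo + 1)
    return out


def _lut_geometry(lut: InverseLUT) -> tuple[float, float]:
    span = float(lut.meta.get("usable_span_mm", 140.0))
    margin = float(lut.meta.get("margin_mm", 30.0))
    return span, margin


def pixel_center_mm(lut: InverseLUT, ix, iy) -> np.ndarray:
    span, margin = _lut_geometry(lut)
    pitch = span / lut.n_pixels
    return np.stack([margin + (np.asarray(ix) + 0.5) * pitch,
                     margin + (np.asarray(iy) + 0.5) * pitch], axis=-1)


class _StrokeBuilder:
    def __init__(self, window: int):
        self.window = window
        self.t: list[float] = []
        self.pixels: list[tuple[int, int]] = []
        self.mm: list[np.ndarray] = []
        self._recent: deque = deque(maxlen=window)

    def add(self, t: float, pixel: tuple[int, int], raw_mm: np.ndarray) -> np.ndarray:
        self._recent.append(raw_mm)
        sm = np.mean(self._recent, axis=0)
        self.t.append(t)
        self.pixels.append(pixel)
        self.mm.append(sm)
        return sm

    def finish(self) -> Stroke:
        return Stroke(np.array(self.t), np.array(self.pixels, dtype=int),
                      np.array(self.mm))


def decode_stream(
    stream: SampleStream,
    lut: InverseLUT,
    cfg: LiftoffConfig = LiftoffConfig(),
    smoothing_window: int = 5,
    hesitation_dwell_s: float = 0.3,
) -> DecodeResult:
    """Segment a sample stream into responses of smoothed strokes.

    Per sample: sum-normalize and look up the pixel.  An off-map read, an
    all-zero (invalid) sample, or a drop-rule lift-off closes the current
    stroke; after a drop-triggered lift, contact resumes once the summed
    counts recover above (1 - drop_fraction) of the last in-contact level.
    A pen-up dwell of ``completion_dwell_s`` completes the response and
    emits a trial-advance event; the stream end flushes any open response.
    """
    sh_stream = stream.meta.get("spec_hash")
    sh_lut = lut.meta.get("spec_hash")
    if sh_stream and sh_lut and str(sh_stream) != str(sh_lut):
        raise ValueError(
            f"map-spec hash mismatch: stream {sh_stream} vs LUT {sh_lut}"
        )
    span, margin = _lut_geometry(lut)
    pitch = span / lut.n_pixels

    n = len(stream)
    table = np.full((n, 6), np.nan)
    responses: list[ResponseRecord] = []
    events: list[tuple[float, int]] = []

    window: deque = deque()      # (t, sum) trailing drop_window_s
    in_contact = False
    lifted_by_drop = False
    last_contact_sum: float | None = None
    pen_up_since: float | None = None
    completed = False

    cur: _StrokeBuilder | None = None
    strokes: list[Stroke] = []

    t0 = time.perf_counter()
    for k in range(n):
        t = float(stream.t[k])
        counts = stream.counts[k]
        s = float(counts.sum())

        valid = s > 0
        pixel = lut.lookup(counts / s) if valid else None

        while window and t - window[0][0] > cfg.drop_window_s:
            window.popleft()
        drop = bool(window) and valid and in_contact and \
            s < (1 - cfg.drop_fraction) * max(w for _, w in window)
        if valid:
            window.append((t, s))

        if not valid or pixel is None:
            pen_down = False
        elif drop:
            pen_down = False
            lifted_by_drop = True
        elif lifted_by_drop and last_contact_sum is not None and \
                s < (1 - cfg.drop_fraction) * last_contact_sum:
            pen_down = False
        else:
            pen_down = True
            lifted_by_drop = False
            last_contact_sum = s

        if pen_down:
            in_contact = True
            pen_up_since = None
            completed = False
            if cur is None:
                cur = _StrokeBuilder(smoothing_window)
            raw_mm = pixel_center_mm(lut, *pixel)
            sm = cur.add(t, pixel, raw_mm)
            table[k] = (t, 1, len(strokes), len(responses), sm[0], sm[1])
        else:
            in_contact = False
            if cur is not None:
                strokes.append(cur.finish())
                cur = None
            if pen_up_since is None:
                pen_up_since = t
            table[k, :4] = (t, 0, -1, len(responses))
            if (not completed and strokes
                    and t - pen_up_since >= cfg.completion_dwell_s):
                resp = ResponseRecord(strokes, completed_at=t)
                resp.metrics = compute_metrics(resp, pitch, hesitation_dwell_s)
                events.append((t, len(responses)))
                responses.append(resp)
                strokes = []
                completed = True

    if cur is not None:
        strokes.append(cur.finish())
    if strokes:
        t_end = float(stream.t[-1]) if n else 0.0
        resp = ResponseRecord(strokes, completed_at=t_end)
        resp.metrics = compute_metrics(resp, pitch, hesitation_dwell_s)
        events.append((t_end, len(responses)))
        responses.append(resp)
    elapsed = time.perf_counter() - t0

    return DecodeResult(
        responses, table, events,
        per_sample_seconds=elapsed / n if n else 0.0,
        meta={"pixel_pitch_mm": pitch, "smoothing_window": smoothing_window},
    )


def compute_metrics(resp: ResponseRecord, pixel_pitch_mm: float,
                    hesitation_dwell_s: float = 0.3) -> StrokeMetrics:
    """Kinematics of a response: lengths, speeds, hesitations, lift-offs.

    Speeds are finite differences of the smoothed positions; a hesitation is
    an in-stroke interval of at least ``hesitation_dwell_s`` during which the
    pen stays within one pixel pitch of where the interval began.
    """
    if not resp.strokes:
        raise ValueError("response has no strokes")
    lengths, means, peaks, hes = [], [], [], []
    down_time = 0.0
    for st in resp.strokes:
        lengths.append(st.path_length_mm)
        down_time += st.duration_s
        if len(st.t) > 1:
            d = np.linalg.norm(np.diff(st.mm, axis=0), axis=1)
            dt = np.diff(st.t)
            means.append(float(d.sum() / (st.t[-1] - st.t[0])))
            peaks.append(float((d / dt).max()))
        else:
            means.append(0.0)
            peaks.append(0.0)
        hes.extend(_find_hesitations(st, pixel_pitch_mm, hesitation_dwell_s))
    return StrokeMetrics(
        stroke_count=len(resp.strokes),
        path_lengths_mm=lengths,
        mean_speeds_mm_s=means,
        peak_speeds_mm_s=peaks,
        hesitations=hes,
        liftoff_count=len(resp.strokes) - 1,
        pen_down_time_s=down_time,
    )


def _find_hesitations(st: Stroke, radius_mm: float, dwell_s: float):
    events = []
    a = 0
    n = len(st.t)
    while a < n:
        b = a
        while b + 1 < n and np.linalg.norm(st.mm[b + 1] - st.mm[a]) < radius_mm:
            b += 1
        dur = float(st.t[b] - st.t[a])
        if b > a and dur >= dwell_s:
            events.append(HesitationEvent(float(st.t[a]), dur))
            a = b + 1
        else:
            a += 1
    return events


# -- rendering ---------------------------------------------------------------

_STROKE_PALETTE = [
    (0, 0, 0), (200, 30, 30), (30, 110, 200), (30, 160, 60),
    (170, 90, 0), (130, 40, 160),
]


def render_response(resp: ResponseRecord, lut: InverseLUT, canvas_px: int = 256,
                    line_width: int = 2, color_by_stroke: bool = False):
    """Draw the response's stroke polylines on a white canvas (PIL image).

    Deterministic: the same record always renders to identical bytes.  With
    ``color_by_stroke`` each stroke cycles through a fixed palette, making
    stroke order visible.
    """
    from PIL import Image, ImageDraw

    if not resp.strokes:
        raise ValueError("response has no strokes")
    span, margin = _lut_geometry(lut)
    img = Image.new("RGB", (canvas_px, canvas_px), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    scale = canvas_px / span
    for si, st in enumerate(resp.strokes):
        pts = [(float((x - margin) * scale), float((y - margin) * scale))
               for x, y in st.mm]
        color = _STROKE_PALETTE[si % len(_STROKE_PALETTE)] if color_by_stroke \
            else (0, 0, 0)
        if len(pts) == 1:
            x, y = pts[0]
            draw.ellipse([x - 1, y - 1, x + 1, y + 1], fill=color)
        else:
            draw.line(pts, fill=color, width=line_width)
    return img


def save_response_images(resp: ResponseRecord, lut: InverseLUT, basename,
                         canvas_px: int = 256) -> None:
    """Write the letter raster as JPEG (acquisition fidelity) and PNG."""
    img = render_response(resp, lut, canvas_px)
    img.save(str(basename) + ".jpg", format="JPEG")
    img.save(str(basename) + ".png", format="PNG")


# -- decoded-stream export ---------------------------------------------------

def write_decoded_tsv(result: DecodeResult, path, lut_meta: dict | None = None) -> None:
    lines = []
    meta = {"pixel_pitch_mm": result.meta.get("pixel_pitch_mm"),
            "smoothing_window": result.meta.get("smoothing_window")}
    if lut_meta:
        meta.update({f"lut_{k}": v for k, v in sorted(lut_meta.items())})
    for key, val in sorted(meta.items()):
        lines.append(f"# {key}={val}")
    lines.append("t_s\tx_mm\ty_mm\tpen_down\tstroke_id\tresponse_id")
    for t, down, sid, rid, x, y in result.sample_table:
        if down > 0:
            lines.append(f"{t:.6f}\t{x:.4f}\t{y:.4f}\t1\t{int(sid)}\t{int(rid)}")
        else:
            lines.append(f"{t:.6f}\tnan\tnan\t0\t-1\t{int(rid)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_events(result: DecodeResult, path) -> None:
    """Trial-advance events, one line per completed response."""
    with open(path, "w") as fh:
        fh.write("t_s\tresponse_id\n")
        for t, rid in result.events:
            fh.write(f"{t:.6f}\t{rid}\n")


# -- straightedge precision experiment ---------------------------------------

def straightedge_experiment(
    spec,
    model: SensorModel,
    lut: InverseLUT,
    line_fractions=(0.15, 0.3, 0.5, 0.7, 0.85),
    speed_mm_s: float = 35.0,
    seed: int = 0,
) -> dict:
    """Drag a simulated pen along straight lines; measure decoded dispersion.

    For each axis, lines of constant perpendicular coordinate are traversed
    across the full usable span (a seeded uniform within-pixel offset is
    added to each line's nominal position).  Per traversal, the standard
    deviation of the decoded perpendicular coordinate is computed about the
    traversal's own mean, separately for samples whose along-axis position
    lies in the central 50% of the span and in the outer quadrants.  The
    error about the true line position is reported alongside.  Decoding here
    is raw per-sample lookup — deliberately unsmoothed, so the dispersion
    reflects the encoding itself, not the rolling average.
    """
    rng = np.random.default_rng(seed)
    span, margin = _lut_geometry(lut)
    pitch = span / lut.n_pixels
    duration = span / speed_mm_s

    regions = {"central": [], "outer": []}     # squared deviations about line mean
    errors = {"central": [], "outer": []}      # deviations about true position
    per_axis = {ax: {"central": [], "outer": []} for ax in ("x", "y")}
    lines = []

    for axis in ("x", "y"):
        for frac in line_fractions:
            perp_true = margin + frac * span + rng.uniform(-0.5, 0.5) * pitch
            perp_true = float(np.clip(perp_true, margin, margin + span))
            if axis == "x":
                wp = ((margin, perp_true), (margin + span, perp_true))
            else:
                wp = ((perp_true, margin), (perp_true, margin + span))
            script = TrajectoryScript((PathSegment(wp, duration),))
            stream = simulate_stream(spec, model, script,
                                     seed=int(rng.integers(0, 2**31 - 1)))
            decoded, along = [], []
            for t, counts in zip(stream.t, stream.counts):
                s = counts.sum()
                if s <= 0:
                    continue
                px = lut.lookup(counts / s)
                if px is None:
                    continue
                mm = pixel_center_mm(lut, *px)
                decoded.append(mm[1] if axis == "x" else mm[0])
                along.append(margin + span * min(t / duration, 1.0))
            decoded = np.asarray(decoded)
            along = np.asarray(along)
            rel = (along - margin) / span
            central = (rel >= 0.25) & (rel <= 0.75)
            rec = {"axis": axis, "perp_true_mm": perp_true}
            for name, mask in (("central", central), ("outer", ~central)):
                vals = decoded[mask]
                if len(vals) > 1:
                    dev = vals - vals.mean()
                    regions[name].extend(dev ** 2)
                    per_axis[axis][name].extend(dev ** 2)
                    errors[name].extend(vals - perp_true)
                    rec[f"{name}_sd_mm"] = float(vals.std(ddof=0))
            lines.append(rec)

    def _sd(sq):
        return float(np.sqrt(np.mean(sq))) if sq else float("nan")

    report = {
        "pixel_pitch_mm": pitch,
        "n_traversals": 2 * len(line_fractions),
        "central_sd_mm": _sd(regions["central"]),
        "outer_sd_mm": _sd(regions["outer"]),
        "central_rmse_mm": _sd([e ** 2 for e in errors["central"]]),
        "outer_rmse_mm": _sd([e ** 2 for e in errors["outer"]]),
        "per_axis": {
            ax: {"central_sd_mm": _sd(per_axis[ax]["central"]),
                 "outer_sd_mm": _sd(per_axis[ax]["outer"])}
            for ax in ("x", "y")
        },
        "lines": lines,
    }
    return report
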