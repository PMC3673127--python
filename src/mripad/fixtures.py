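"""Deterministic trajectory-script fixtures with recorded ground truth.

Synthetic stand-ins for subject responses: block letters ("H", "T", "c",
"b"), a straightedge traversal set and a mid-stroke hesitation scenario.
Each fixture carries the ground truth a decoder should recover (stroke
count, approximate path length), so end-to-end tests can grade themselves.
All waypoints lie within the usable span; letters are drawn over-sized, as
subjects write on the pad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colormap import ColorMapSpec
from .sensor import PathSegment, PenUpSegment, TrajectoryScript


@dataclass(frozen=True)
class Fixture:
    name: str
    script: TrajectoryScript
    stroke_count: int
    path_length_mm: float
    hesitation_count: int = 0


def _letter_box(spec: ColorMapSpec):
    # A 100 mm tall, 60 mm wide writing box centred in the usable span.
    cx, cy = spec.side_mm / 2.0, spec.side_mm / 2.0
    return cx - 30.0, cx + 30.0, cy - 50.0, cy + 50.0


def _strokes_script(strokes, speed_mm_s: float = 70.0,
                    gap_s: float = 0.4) -> TrajectoryScript:
    segs = []
    for wp in strokes:
        wp = np.asarray(wp, dtype=float)
        length = float(np.linalg.norm(np.diff(wp, axis=0), axis=1).sum())
        segs.append(PathSegment(tuple(map(tuple, wp)), max(length / speed_mm_s, 0.2)))
        segs.append(PenUpSegment(gap_s))
    return TrajectoryScript(tuple(segs[:-1]))  # no trailing pen-up


def make_fixture_scripts(spec: ColorMapSpec | None = None) -> dict:
    """Library of named fixtures: letters, straightedges, hesitation."""
    spec = spec or ColorMapSpec()
    x0, x1, y0, y1 = _letter_box(spec)
    ym = (y0 + y1) / 2.0
    fixtures: dict[str, Fixture] = {}

    # H: two verticals then the crossbar — 3 strokes.
    h_strokes = [
        [(x0, y0), (x0, y1)],
        [(x1, y0), (x1, y1)],
        [(x0, ym), (x1, ym)],
    ]
    fixtures["H"] = Fixture("H", _strokes_script(h_strokes), 3,
                            2 * (y1 - y0) + (x1 - x0))

    # T: top bar then vertical — 2 strokes.
    t_strokes = [
        [(x0, y0), (x1, y0)],
        [((x0 + x1) / 2, y0), ((x0 + x1) / 2, y1)],
    ]
    fixtures["T"] = Fixture("T", _strokes_script(t_strokes), 2,
                            (x1 - x0) + (y1 - y0))

    # c: a single open arc.
    theta = np.linspace(np.pi * 0.3, np.pi * 1.7, 24)
    r = (x1 - x0) / 2.0
    arc = np.stack([(x0 + x1) / 2 + r * np.cos(theta),
                    ym + r * np.sin(theta)], axis=-1)
    fixtures["c"] = Fixture(
        "c", _strokes_script([arc]), 1,
        float(np.linalg.norm(np.diff(arc, axis=0), axis=1).sum()))

    # b: vertical spine then the bowl — 2 strokes.
    bowl_theta = np.linspace(-np.pi / 2, np.pi / 2, 16)
    br = (x1 - x0) / 2.0
    bowl = np.stack([x0 + br * np.cos(bowl_theta),
                     ym + br / 1.5 * np.sin(bowl_theta) + 20.0], axis=-1)
    b_strokes = [np.array([(x0, y0), (x0, y1)]), bowl]
    fixtures["b"] = Fixture(
        "b", _strokes_script(b_strokes), 2,
        (y1 - y0) + float(np.linalg.norm(np.diff(bowl, axis=0), axis=1).sum()))

    # Straightedge set: 5 constant-y lines spanning the usable area.
    m = spec.margin_mm
    span = spec.usable_span_mm
    edge_strokes = [
        [(m, m + f * span), (m + span, m + f * span)]
        for f in (0.15, 0.3, 0.5, 0.7, 0.85)
    ]
    fixtures["straightedge"] = Fixture(
        "straightedge",
        _strokes_script(edge_strokes, speed_mm_s=35.0, gap_s=1.5),
        5, 5 * span)

    # Hesitation: a straight stroke with a 1 s stationary mid-stroke dwell.
    seg_len = 50.0
    hx, hy = spec.side_mm / 2.0, spec.side_mm / 2.0
    seg1 = PathSegment(((hx - seg_len, hy), (hx, hy)), seg_len / 70.0)
    dwell = PathSegment(((hx, hy),), 1.0)
    seg2 = PathSegment(((hx, hy), (hx + seg_len, hy)), seg_len / 70.0)
    fixtures["hesitation"] = Fixture(
        "hesitation", TrajectoryScript((seg1, dwell, seg2)), 1,
        2 * seg_len, hesitation_count=1)

    for fx in fixtures.values():
        fx.script.validate_span(spec)
    return fixtures
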