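"""Ideal printed color map: position -> color.

The writing surface is a square print whose color varies continuously with
position.  Three linear pigment gradients (cyan, magenta, yellow — the
printer's native pigments), with axes oriented 120 degrees apart, overlap so
that a local color read determines position uniquely.  Each gradient is
restricted to a byte sub-range away from both paper white and pigment
saturation, where channel response is most sensitive.

Because the three axis unit vectors sum to zero, the total pigment load
C + M + Y is constant over the map, so the RGB channel sum is constant too
and the sum-normalized chromaticity is an affine, injective function of
position.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

PIGMENTS = ("cyan", "magenta", "yellow")

#: Diameter of the acrylic guide disc at the pen tip (2 inches), which keeps
#: the pen center away from the frame edge.
GUIDE_DISC_MM = 50.8


class OffMapError(ValueError):
    """A queried position lies outside the printed map."""


@dataclass(frozen=True)
class GradientSpec:
    """One pigment's linear gradient: direction and byte range."""

    pigment: str
    axis_angle_deg: float
    low_byte: int = 0x20
    high_byte: int = 0xD0

    def __post_init__(self) -> None:
        if self.pigment not in PIGMENTS:
            raise ValueError(f"unknown pigment {self.pigment!r}")
        if not (0 <= self.low_byte < self.high_byte <= 255):
            raise ValueError(
                f"{self.pigment}: need 0 <= low_byte < high_byte <= 255, "
                f"got [{self.low_byte}, {self.high_byte}]"
            )
        object.__setattr__(self, "axis_angle_deg", float(self.axis_angle_deg) % 360.0)

    @property
    def axis_unit(self) -> np.ndarray:
        a = math.radians(self.axis_angle_deg)
        return np.array([math.cos(a), math.sin(a)])


def _default_gradients() -> tuple[GradientSpec, GradientSpec, GradientSpec]:
    return (
        GradientSpec("cyan", 0.0),
        GradientSpec("magenta", 120.0),
        GradientSpec("yellow", 240.0),
    )


@dataclass(frozen=True)
class ColorMapSpec:
    """Geometry and gradients of the printed map.

    Coordinates: origin at the map's top-left corner (the frame's marked top
    edge), x rightward, y downward, millimetres.  The usable span is the
    central area reachable by the pen center given the guide disc.
    """

    side_mm: float = 200.0
    usable_span_mm: float = 140.0
    gradients: tuple[GradientSpec, ...] = field(default_factory=_default_gradients)
    off_map_color: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if not (0 < self.usable_span_mm <= self.side_mm):
            raise ValueError("need 0 < usable_span_mm <= side_mm")
        pigs = sorted(g.pigment for g in self.gradients)
        if pigs != sorted(PIGMENTS):
            raise ValueError("need exactly one GradientSpec per pigment")
        angles = sorted(g.axis_angle_deg for g in self.gradients)
        diffs = sorted((b - a) % 360.0 for a in angles for b in angles)
        want = sorted([0.0, 0.0, 0.0, 120.0, 120.0, 120.0, 240.0, 240.0, 240.0])
        if not np.allclose(diffs, want, atol=1e-9):
            raise ValueError(
                "gradient axis angles must be pairwise 120 degrees apart; "
                f"got {angles}"
            )

    @property
    def margin_mm(self) -> float:
        """Offset of the usable span from the frame edge (each side)."""
        return (self.side_mm - self.usable_span_mm) / 2.0

    @property
    def center(self) -> np.ndarray:
        return np.array([self.side_mm / 2.0, self.side_mm / 2.0])

    def ordered_gradients(self) -> tuple[GradientSpec, ...]:
        """Gradients in fixed (cyan, magenta, yellow) order."""
        by_pig = {g.pigment: g for g in self.gradients}
        return tuple(by_pig[p] for p in PIGMENTS)


def reachable_span_mm(
    side_mm: float = 200.0, disc_diameter_mm: float = GUIDE_DISC_MM
) -> float:
    """Span reachable by the pen center: frame side minus the guide disc.

    The disc's rim hits the frame when the pen center is a disc radius from
    each edge, so the center can cover ``side_mm - disc_diameter_mm``.
    """
    return side_mm - disc_diameter_mm


def on_map(spec: ColorMapSpec, positions: np.ndarray) -> np.ndarray:
    """Boolean mask, True where positions (..., 2) lie within the frame."""
    p = np.asarray(positions, dtype=float)
    return (p >= 0.0).all(axis=-1) & (p <= spec.side_mm).all(axis=-1)


def in_usable_span(spec: ColorMapSpec, positions: np.ndarray) -> np.ndarray:
    p = np.asarray(positions, dtype=float)
    m = spec.margin_mm
    return (p >= m).all(axis=-1) & (p <= m + spec.usable_span_mm).all(axis=-1)


def pigment_field(spec: ColorMapSpec, positions: np.ndarray) -> np.ndarray:
    """Continuous CMY pigment values at positions (..., 2) -> (..., 3).

    Each pigment is affine in the projection of the position onto its axis:
    low_byte at projection 0, high_byte at projection side_mm, where the
    projection is referenced so the map center sits at side_mm / 2.  The
    field is constant perpendicular to the axis and is returned un-rounded
    and un-clipped (byte clipping happens at raster time).

    Raises :class:`OffMapError` if any position lies outside the frame.
    """
    p = np.asarray(positions, dtype=float)
    if p.shape[-1] != 2:
        raise ValueError("positions must have trailing dimension 2")
    if not np.all(on_map(spec, p)):
        raise OffMapError("position outside the color map frame")
    rel = p - spec.center
    out = np.empty(p.shape[:-1] + (3,), dtype=float)
    for k, g in enumerate(spec.ordered_gradients()):
        proj = rel @ g.axis_unit + spec.side_mm / 2.0
        out[..., k] = g.low_byte + (g.high_byte - g.low_byte) * proj / spec.side_mm
    return out


def ideal_color_float(spec: ColorMapSpec, positions: np.ndarray) -> np.ndarray:
    """Continuous RGB reflectance at positions; off-map -> off_map_color.

    Subtractive pigment model: R = 255 - C, G = 255 - M, B = 255 - Y,
    clipped to [0, 255] but not rounded (the simulator averages this field).
    """
    p = np.asarray(positions, dtype=float)
    mask = on_map(spec, p)
    out = np.empty(p.shape[:-1] + (3,), dtype=float)
    out[...] = np.asarray(spec.off_map_color, dtype=float)
    if np.any(mask):
        safe = np.where(mask[..., None], p, spec.center)
        cmy = pigment_field(spec, safe)
        rgb = np.clip(255.0 - cmy, 0.0, 255.0)
        out[mask] = rgb[mask]
    return out


def ideal_color_at(spec: ColorMapSpec, positions: np.ndarray) -> np.ndarray:
    """RGB bytes at positions (..., 2) -> (..., 3) uint8.

    Rounding is half-up to the nearest byte level; off-map positions get
    ``spec.off_map_color``.
    """
    rgb = ideal_color_float(spec, positions)
    return np.floor(rgb + 0.5).clip(0, 255).astype(np.uint8)


def render_map_raster(spec: ColorMapSpec, dots_per_mm: float = 11.81) -> np.ndarray:
    """Render the map to an (n, n, 3) uint8 raster, n = side_mm * dots_per_mm.

    Row i is the strip of the map at y ~ (i + 0.5) / dots_per_mm: row index
    increases downward, matching the map's top-left-origin convention.
    """
    if not dots_per_mm > 0:
        raise ValueError("dots_per_mm must be positive")
    n = int(round(spec.side_mm * dots_per_mm))
    coords = (np.arange(n) + 0.5) / dots_per_mm
    xx, yy = np.meshgrid(coords, coords)
    pos = np.stack([xx, yy], axis=-1)
    return ideal_color_at(spec, pos)


# -- spec file I/O (flat key-value text) ------------------------------------

def spec_to_text(spec: ColorMapSpec) -> str:
    lines = [
        f"side_mm={spec.side_mm:g}",
        f"usable_span_mm={spec.usable_span_mm:g}",
        "off_map_color={:d},{:d},{:d}".format(*spec.off_map_color),
    ]
    for g in spec.ordered_gradients():
        lines.append(
            f"{g.pigment}_angle_deg={g.axis_angle_deg:g}"
        )
        lines.append(f"{g.pigment}_low_byte={g.low_byte}")
        lines.append(f"{g.pigment}_high_byte={g.high_byte}")
    return "\n".join(lines) + "\n"


def spec_from_text(text: str) -> ColorMapSpec:
    kv: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    grads = tuple(
        GradientSpec(
            p,
            float(kv[f"{p}_angle_deg"]),
            int(kv[f"{p}_low_byte"]),
            int(kv[f"{p}_high_byte"]),
        )
        for p in PIGMENTS
    )
    off = tuple(int(v) for v in kv.get("off_map_color", "255,255,255").split(","))
    return ColorMapSpec(
        side_mm=float(kv.get("side_mm", 200.0)),
        usable_span_mm=float(kv.get("usable_span_mm", 140.0)),
        gradients=grads,
        off_map_color=off,  # type: ignore[arg-type]
    )


def write_spec(spec: ColorMapSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(spec_to_text(spec))


def read_spec(path) -> ColorMapSpec:
    with open(path) as fh:
        return spec_from_text(fh.read())


def spec_hash(spec: ColorMapSpec) -> str:
    """Short stable digest of the spec, used to chain-validate artifacts."""
    return hashlib.sha256(spec_to_text(spec).encode()).hexdigest()[:12]


def save_map_png(spec: ColorMapSpec, path, dots_per_mm: float = 11.81) -> None:
    """Write the printable map as PNG plus a sidecar ``<path>.spec.txt``."""
    from PIL import Image

    raster = render_map_raster(spec, dots_per_mm)
    Image.fromarray(raster, mode="RGB").save(path, format="PNG")
    write_spec(spec, str(path) + ".spec.txt")
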