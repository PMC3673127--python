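"""Chromaticity normalization, guided calibration, forward interpolation.

Overall luminance of the sensed light is hostage to fiber bending, supply
variation and map wear, so raw (R, G, B) counts are never used directly:
each channel is divided by the channel sum, leaving a two-degree-of-freedom
chromaticity that is invariant to any common multiplicative factor.

Calibration samples the map at a small regular grid (5 x 5 by default — a
compromise between exhaustive sampling and quick recalibration) and the
forward map interpolates that grid to a full N x N pixel lattice with
separable 2nd-order polynomial least-squares fits, per channel, first along
one axis and then along the other.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .colormap import ColorMapSpec, spec_hash

DEFAULT_GRID_N = 5
DEFAULT_SAMPLES_PER_POINT = 30  # ~1 s of data at 30 samples/s
DEFAULT_PIXELS_PER_AXIS = 32


class InvalidSampleError(ValueError):
    """All-zero counts carry no chromaticity (treated as pen-up upstream)."""


class CalibrationError(RuntimeError):
    pass


def normalize_chromaticity(counts: np.ndarray) -> np.ndarray:
    """Divide each channel by the channel sum; output sums to 1.

    Accepts a single (3,) triple or an (..., 3) array.  Raises
    :class:`InvalidSampleError` if any sum is non-positive.
    """
    c = np.asarray(counts, dtype=float)
    s = c.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise InvalidSampleError("non-positive channel sum")
    return c / s


def calibration_grid(spec: ColorMapSpec, grid_n: int = DEFAULT_GRID_N) -> np.ndarray:
    """(grid_n**2, 2) prompt positions in frame mm, row-major from the top edge.

    Endpoints sit on the usable-span boundary; the first position is the
    top-left usable corner.
    """
    if grid_n < 3:
        raise ValueError("grid_n must be >= 3 (quadratic fits need 3 points per axis)")
    lo = spec.margin_mm
    coords = np.linspace(lo, lo + spec.usable_span_mm, grid_n)
    xx, yy = np.meshgrid(coords, coords)  # rows: constant y, top first
    return np.stack([xx.ravel(), yy.ravel()], axis=-1)


@dataclass
class CalibrationTable:
    grid_n: int
    positions: np.ndarray   # (grid_n**2, 2) frame mm, row-major
    chroma: np.ndarray      # (grid_n**2, 3), each row sums to 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.positions) != self.grid_n ** 2:
            raise ValueError("positions do not fill the grid")
        if self.chroma.shape != (self.grid_n ** 2, 3):
            raise ValueError("need one chromaticity per grid position")
        if not np.all(np.isfinite(self.chroma)):
            raise ValueError("non-finite chromaticity in table")

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.positions[: self.grid_n, 0]
        ys = self.positions[:: self.grid_n, 1]
        return xs, ys


def collect_calibration(
    sampler,
    positions: np.ndarray,
    samples_per_point: int = DEFAULT_SAMPLES_PER_POINT,
    meta: dict | None = None,
) -> CalibrationTable:
    """Prompt-and-average loop over the grid positions.

    ``sampler(position, n)`` must return an (m, 3) array of raw counts for a
    pen held at ``position``.  Each sample is sum-normalized first, then the
    chromaticities are averaged and renormalized — per-sample luminance
    therefore cannot weight the average.
    """
    grid_n = int(round(np.sqrt(len(positions))))
    chroma = np.empty((len(positions), 3))
    for idx, pos in enumerate(positions):
        raw = np.asarray(sampler(pos, samples_per_point), dtype=float)
        valid = raw[raw.sum(axis=1) > 0]
        if len(valid) < samples_per_point:
            raise CalibrationError(
                f"calibration aborted: point {idx} at {tuple(pos)} produced "
                f"{len(valid)} valid samples, need {samples_per_point}"
            )
        mean = normalize_chromaticity(valid).mean(axis=0)
        chroma[idx] = mean / mean.sum()
    out_meta = {"samples_per_point": samples_per_point}
    if meta:
        out_meta.update(meta)
    return CalibrationTable(grid_n, np.asarray(positions, float), chroma, out_meta)


@dataclass
class ForwardMap:
    """Calibrated chromaticity at every pixel center of the usable span.

    ``chroma[iy, ix]`` is the chromaticity at pixel (ix, iy); pixel (ix, iy)
    covers the half-open cell [ix*pitch, (ix+1)*pitch) x [iy*pitch, ...) of
    the usable span, and its center lies at margin + (i + 0.5) * pitch in
    frame mm.
    """

    n_pixels: int
    chroma: np.ndarray          # (N, N, 3) indexed [iy, ix]
    usable_span_mm: float
    margin_mm: float
    meta: dict = field(default_factory=dict)

    @property
    def pixel_pitch_mm(self) -> float:
        return self.usable_span_mm / self.n_pixels

    def pixel_center_mm(self, ix, iy) -> np.ndarray:
        pitch = self.pixel_pitch_mm
        return np.stack(
            [self.margin_mm + (np.asarray(ix) + 0.5) * pitch,
             self.margin_mm + (np.asarray(iy) + 0.5) * pitch], axis=-1)

    def pixel_centers_axis(self) -> np.ndarray:
        pitch = self.pixel_pitch_mm
        return self.margin_mm + (np.arange(self.n_pixels) + 0.5) * pitch


def _quad_eval(x_fit: np.ndarray, y_fit: np.ndarray, x_eval: np.ndarray) -> np.ndarray:
    # Least-squares quadratic through (x_fit, y_fit) evaluated at x_eval.
    # Coordinates are centred/scaled for conditioning; y_fit may be 2-D
    # (one fit per column).
    x0 = x_fit.mean()
    s = max(np.abs(x_fit - x0).max(), 1.0)
    u = (x_fit - x0) / s
    v = (x_eval - x0) / s
    design = np.vander(u, 3, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y_fit, rcond=None)
    return np.vander(v, 3, increasing=True) @ coef


def interpolate_forward(
    table: CalibrationTable,
    n_pixels: int = DEFAULT_PIXELS_PER_AXIS,
    axis_order: str = "xy",
) -> ForwardMap:
    """Separable per-channel quadratic interpolation of the calibration grid.

    For each channel independently: fit a least-squares quadratic along every
    grid row (first axis), evaluate it at all pixel-center coordinates, then
    fit quadratics along the resulting columns (second axis).  Finally each
    pixel's three channels are renormalized to sum 1.  ``axis_order`` selects
    which axis is fitted first ("xy" or "yx").
    """
    if n_pixels < table.grid_n:
        raise ValueError("n_pixels must be >= grid_n")
    if axis_order not in ("xy", "yx"):
        raise ValueError("axis_order must be 'xy' or 'yx'")
    xs, ys = table.axis_coords()
    usable = float(xs[-1] - xs[0])
    margin = float(xs[0])
    pitch = usable / n_pixels
    centers = margin + (np.arange(n_pixels) + 0.5) * pitch

    g = table.grid_n
    vals = table.chroma.reshape(g, g, 3)  # [row=y, col=x, channel]
    out = np.empty((n_pixels, n_pixels, 3))
    for ch in range(3):
        grid = vals[:, :, ch]
        if axis_order == "xy":
            # pass 1 along x (per row), pass 2 along y (per pixel column)
            inter = _quad_eval(xs, grid.T, centers).T         # (g, N)
            out[:, :, ch] = _quad_eval(ys, inter, centers)    # (N, N)
        else:
            inter = _quad_eval(ys, grid, centers)             # (N, g) -> rows y
            out[:, :, ch] = _quad_eval(xs, inter.T, centers).T
    out /= out.sum(axis=2, keepdims=True)
    meta = dict(table.meta)
    meta.update({"grid_n": g, "axis_order": axis_order})
    return ForwardMap(n_pixels, out, usable, margin, meta)


def calibrate_simulated(
    spec: ColorMapSpec,
    model,
    grid_n: int = DEFAULT_GRID_N,
    samples_per_point: int = DEFAULT_SAMPLES_PER_POINT,
    seed: int = 0,
) -> CalibrationTable:
    """Convenience: run the guided calibration against the simulator."""
    from .sensor import stationary_sampler

    positions = calibration_grid(spec, grid_n)
    sampler = stationary_sampler(spec, model, seed)
    return collect_calibration(
        sampler, positions, samples_per_point,
        meta={"grid_n": grid_n, "spec_hash": spec_hash(spec), "seed": seed},
    )


# -- calibration file format -------------------------------------------------

def write_calibration(table: CalibrationTable, path) -> None:
    buf = io.StringIO()
    meta = dict(table.meta)
    meta.setdefault("grid_n", table.grid_n)
    for key, val in sorted(meta.items()):
        buf.write(f"# {key}={val}\n")
    buf.write("x_mm\ty_mm\tr\tg\tb\n")
    for (x, y), (r, g, b) in zip(table.positions, table.chroma):
        buf.write(f"{x:.4f}\t{y:.4f}\t{r:.12f}\t{g:.12f}\t{b:.12f}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_calibration(path) -> CalibrationTable:
    meta: dict = {}
    pos, chroma = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("x_mm"):
                continue
            f = [float(v) for v in line.split("\t")]
            pos.append(f[:2])
            chroma.append(f[2:5])
    grid_n = int(meta.get("grid_n", round(np.sqrt(len(pos)))))
    return CalibrationTable(grid_n, np.asarray(pos), np.asarray(chroma), meta)
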