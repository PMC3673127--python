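"""Inverse lookup: quantized chromaticity -> pixel position.

The forward map assigns a chromaticity to each pixel — approximately a
planar cut through color space.  Decoding needs the inverse, so the cut is
"fleshed out": every quantized triple near the calibrated surface is
assigned the position of the nearest assigned triple, out to a bounded
projection depth (+/-5% of the channel range by default, per channel
independently).  Colors beyond that envelope stay unassigned, and reading
one is itself a usable signal: the pen has left the map.  The depth is a
deliberate trade-off between strict off-map rejection (robust lift-off
detection) and tolerance of sensor noise.

The table is built over sum-normalized chromaticity (the quantity actually
used to determine position), quantized to ``bins_per_channel`` levels so the
per-channel byte-space tolerance semantics carry over; that choice is
recorded in the LUT file header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .calibration import ForwardMap

DEFAULT_BINS = 256
DEFAULT_PROJECTION_DEPTH = 0.05

SEED = "S"
PROJECTED = "P"

#: Sentinel for a chromaticity with no assigned position.
OFF_MAP = None


class LUTBuildError(RuntimeError):
    pass


def quantize_chroma(chroma: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Map chromaticity in [0, 1] to integer levels in [0, bins-1].

    level = floor(c * (bins - 1) + 0.5), i.e. round-half-up onto a byte-like
    grid (for bins = 256 this is the usual byte quantization of a unit value).
    """
    c = np.asarray(chroma, dtype=float)
    return np.floor(c * (bins - 1) + 0.5).clip(0, bins - 1).astype(np.int64)


def dequantize(levels: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    return np.asarray(levels, dtype=float) / (bins - 1)


def _encode(q: np.ndarray, bins: int) -> np.ndarray:
    q = np.asarray(q, dtype=np.int64)
    return (q[..., 0] * bins + q[..., 1]) * bins + q[..., 2]


def _decode(keys: np.ndarray, bins: int) -> np.ndarray:
    keys = np.asarray(keys, dtype=np.int64)
    qb = keys % bins
    rest = keys // bins
    qg = rest % bins
    qr = rest // bins
    return np.stack([qr, qg, qb], axis=-1)


@dataclass
class InverseLUT:
    bins_per_channel: int
    projection_depth: float
    n_pixels: int
    entries: dict            # encoded key -> (ix, iy, provenance)
    meta: dict = field(default_factory=dict)

    @property
    def seed_count(self) -> int:
        return sum(1 for v in self.entries.values() if v[2] == SEED)

    @property
    def projected_count(self) -> int:
        return sum(1 for v in self.entries.values() if v[2] == PROJECTED)

    def lookup(self, chroma) -> tuple[int, int] | None:
        """Pixel (ix, iy) for this chromaticity, or OFF_MAP (None)."""
        key = int(_encode(quantize_chroma(chroma, self.bins_per_channel),
                          self.bins_per_channel))
        hit = self.entries.get(key)
        return None if hit is None else (hit[0], hit[1])

    def lookup_quantized(self, q) -> tuple[int, int] | None:
        hit = self.entries.get(int(_encode(np.asarray(q), self.bins_per_channel)))
        return None if hit is None else (hit[0], hit[1])


def lookup(lut: InverseLUT, chroma) -> tuple[int, int] | None:
    return lut.lookup(chroma)


def _seed_table(fwd: ForwardMap, bins: int):
    """Quantize the forward map; first (iy, ix) in scan order wins a collision."""
    n = fwd.n_pixels
    q = quantize_chroma(fwd.chroma, bins)          # (N, N, 3) indexed [iy, ix]
    keys = _encode(q, bins).ravel()                # scan order: iy-major
    entries: dict[int, tuple[int, int, str]] = {}
    collisions = 0
    for flat, key in enumerate(keys):
        key = int(key)
        if key in entries:
            collisions += 1
        else:
            iy, ix = divmod(flat, n)
            entries[key] = (ix, iy, SEED)
    return entries, collisions


def build_lut(
    fwd: ForwardMap,
    bins: int = DEFAULT_BINS,
    projection_depth: float = DEFAULT_PROJECTION_DEPTH,
) -> InverseLUT:
    """Seed the LUT from the forward map, then project outward.

    Seeding: quantize(fwd[iy, ix]) -> (ix, iy); colliding pixels keep the
    lexicographically smallest (iy, ix), and a collision rate above 1% of
    pixels fails the build (the map is not injective enough at this
    quantization).

    Projection: every unassigned triple whose Euclidean-nearest seed (ties:
    smaller Euclidean, then smaller (iy, ix)) lies within
    ``projection_depth * (bins - 1)`` in every channel independently receives
    that seed's pixel; all other triples remain unassigned (off-map).
    """
    entries, collisions = _seed_table(fwd, bins)
    n_px = fwd.n_pixels ** 2
    if collisions > 0.01 * n_px:
        raise LUTBuildError(
            f"{collisions} of {n_px} pixels collide after quantization; "
            "the forward map is not injective enough at this bin count"
        )

    seed_keys = np.fromiter(entries.keys(), dtype=np.int64, count=len(entries))
    # Seed array ordered by (iy, ix) so argmin's first-minimum rule implements
    # the lexicographic tie-break.
    order = np.argsort([entries[int(k)][1] * fwd.n_pixels + entries[int(k)][0]
                        for k in seed_keys], kind="stable")
    seed_keys = seed_keys[order]
    seed_q = _decode(seed_keys, bins).astype(np.float32)
    seed_px = np.array([entries[int(k)][:2] for k in seed_keys], dtype=np.int64)

    depth = projection_depth * (bins - 1)
    d_int = int(np.floor(depth + 1e-12))

    # Candidates: union of (2*d_int+1)^3 cubes around the seeds, deduplicated.
    off_1d = np.arange(-d_int, d_int + 1, dtype=np.int64)
    offsets = np.stack(np.meshgrid(off_1d, off_1d, off_1d, indexing="ij"),
                       axis=-1).reshape(-1, 3)
    seeds_int = seed_q.astype(np.int64)
    cand_keys: list[np.ndarray] = []
    chunk = max(1, 4_000_000 // max(len(seeds_int), 1))
    for lo in range(0, len(offsets), chunk):
        c = seeds_int[None, :, :] + offsets[lo:lo + chunk, None, :]
        ok = ((c >= 0) & (c < bins)).all(axis=-1)
        cand_keys.append(_encode(c, bins)[ok])
    cand = np.unique(np.concatenate(cand_keys)) if cand_keys else np.empty(0, np.int64)
    cand = cand[~np.isin(cand, np.sort(seed_keys))]

    cq = _decode(cand, bins).astype(np.float32)
    # Exact integer arithmetic in float32: all squared distances < 2**24.
    s_norm = (seed_q ** 2).sum(axis=1)
    nearest = np.empty(len(cq), dtype=np.int64)
    step = 20_000
    for lo in range(0, len(cq), step):
        block = cq[lo:lo + step]
        d2 = (block ** 2).sum(axis=1)[:, None] - 2.0 * block @ seed_q.T + s_norm[None, :]
        nearest[lo:lo + step] = np.argmin(d2, axis=1)
    within = (np.abs(cq - seed_q[nearest]) <= depth + 1e-9).all(axis=1)
    for key, idx in zip(cand[within], nearest[within]):
        ix, iy = seed_px[idx]
        entries[int(key)] = (int(ix), int(iy), PROJECTED)

    return InverseLUT(bins, projection_depth, fwd.n_pixels, entries, {
        "collisions": collisions,
        "usable_span_mm": fwd.usable_span_mm,
        "margin_mm": fwd.margin_mm,
        **{k: v for k, v in fwd.meta.items() if k in ("spec_hash", "grid_n")},
    })


# -- LUT file format ---------------------------------------------------------

def write_lut(lut: InverseLUT, path) -> None:
    """Text table sorted by (qr, qg, qb) for bit-exact reproducibility."""
    buf = io.StringIO()
    meta = {
        "bins_per_channel": lut.bins_per_channel,
        "projection_depth": lut.projection_depth,
        "n_pixels": lut.n_pixels,
        "seed_count": lut.seed_count,
        "projected_count": lut.projected_count,
        "chroma_space": "sum-normalized",
        **lut.meta,
    }
    for key, val in sorted(meta.items()):
        buf.write(f"# {key}={val}\n")
    buf.write("qr\tqg\tqb\ti\tj\tprovenance\n")
    bins = lut.bins_per_channel
    for key in sorted(lut.entries):
        qr, qg, qb = _decode(np.int64(key), bins)
        ix, iy, prov = lut.entries[key]
        buf.write(f"{qr}\t{qg}\t{qb}\t{ix}\t{iy}\t{prov}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_lut(path) -> InverseLUT:
    meta: dict = {}
    entries: dict[int, tuple[int, int, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("qr"):
                continue
            qr, qg, qb, ix, iy, prov = line.split("\t")
            bins = int(meta["bins_per_channel"])
            q = np.array([int(qr), int(qg), int(qb)])
            entries[int(_encode(q, bins))] = (int(ix), int(iy), prov)
    lut = InverseLUT(
        int(meta.pop("bins_per_channel")),
        float(meta.pop("projection_depth")),
        int(meta.pop("n_pixels")),
        entries,
    )
    meta.pop("seed_count", None)
    meta.pop("projected_count", None)
    meta.pop("chroma_space", None)
    for key in ("usable_span_mm", "margin_mm"):
        if key in meta:
            meta[key] = float(meta[key])
    if "collisions" in meta:
        meta["collisions"] = int(meta["collisions"])
    lut.meta = meta
    return lut
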