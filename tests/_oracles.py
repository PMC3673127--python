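"""Independent brute-force oracles, kept deliberately naive.

These re-derive expected values from first principles (direct scans, normal
equations, Monte-Carlo integration) without touching the production code
paths they check.
"""

import numpy as np


def pigment_projection_oracle(position, center, side_mm, angles_deg, low, high):
    """Direct dot-product-with-unit-vector projection arithmetic."""
    pos = np.asarray(position, dtype=float)
    out = []
    for ang in angles_deg:
        u = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
        proj = float(np.dot(pos - center, u)) + side_mm / 2.0
        out.append(low + (high - low) * proj / side_mm)
    return np.array(out)


def quad_fit_normal_equations(x, y, x_eval):
    """Least-squares quadratic via explicitly assembled normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.stack([np.ones_like(x), x, x * x], axis=1)
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    xe = np.asarray(x_eval, dtype=float)
    return coef[0] + coef[1] * xe + coef[2] * xe * xe


def disc_mean_monte_carlo(field, center, radius, n=200_000, seed=0):
    """Monte-Carlo mean of ``field`` over a uniform disc."""
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, size=n)
    pts = np.asarray(center, float) + np.stack(
        [r * np.cos(th), r * np.sin(th)], axis=-1)
    return field(pts).mean(axis=0)


def brute_force_lut_entries(fwd_chroma, bins, projection_depth):
    """All-triples-vs-all-seeds construction of the inverse LUT.

    For every quantized triple in the B^3 cube: find the Euclidean-nearest
    seed (ties: lexicographically smallest (iy, ix) pixel); assign the
    triple iff every channel is within depth*(bins-1) of that seed.
    Returns dict key-tuple -> (ix, iy, provenance).
    """
    n = fwd_chroma.shape[0]
    q = np.floor(fwd_chroma * (bins - 1) + 0.5).clip(0, bins - 1).astype(int)

    seeds = {}   # triple -> (ix, iy); first (iy, ix) in scan order wins
    for iy in range(n):
        for ix in range(n):
            key = tuple(q[iy, ix])
            if key not in seeds:
                seeds[key] = (ix, iy)
    seed_list = sorted(seeds.items(), key=lambda kv: (kv[1][1], kv[1][0]))
    seed_arr = np.array([k for k, _ in seed_list], dtype=float)
    seed_px = [p for _, p in seed_list]

    depth = projection_depth * (bins - 1)
    entries = {}
    for key, px in seeds.items():
        entries[key] = (px[0], px[1], "S")

    grid = np.arange(bins)
    for qr in grid:
        plane = np.stack(np.meshgrid(grid, grid, indexing="ij"), axis=-1)
        triples = np.concatenate(
            [np.full((bins, bins, 1), qr), plane], axis=-1).reshape(-1, 3)
        d2 = ((triples[:, None, :] - seed_arr[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)       # first min = smallest (iy, ix)
        cheb_ok = (np.abs(triples - seed_arr[nearest]) <= depth + 1e-9).all(axis=1)
        for tri, near, ok in zip(triples, nearest, cheb_ok):
            key = tuple(int(v) for v in tri)
            if key in entries or not ok:
                continue
            ix, iy = seed_px[near]
            entries[key] = (ix, iy, "P")
    return entries
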