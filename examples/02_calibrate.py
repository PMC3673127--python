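"""Guided 5x5 calibration against the simulated pen, then interpolation.

Each grid point is held for ~1 s (30 samples); chromaticities are averaged
and the grid is interpolated to a 32x32 pixel lattice with separable
2nd-order polynomial fits.
"""

import mripad as mp

spec = mp.ColorMapSpec()
model = mp.SensorModel()          # default noise and drift

table = mp.calibrate_simulated(spec, model, grid_n=5, seed=1)
xs = sorted({float(x) for x in table.positions[:, 0]})
print(f"calibrated {table.grid_n}x{table.grid_n} grid, x coordinates {xs} mm")
print(f"top-left chroma: {table.chroma[0].round(4)} (sums to 1)")

fwd = mp.interpolate_forward(table, n_pixels=32)
print(f"forward map: {fwd.n_pixels}x{fwd.n_pixels} pixels, "
      f"pitch {fwd.pixel_pitch_mm:.3f} mm/pixel")
# The pitch is the spatial resolution of everything decoded downstream.
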