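"""Render the printable color map and its spec sidecar.

Three pigment gradients at 120 degrees overlap so that every position in
the usable area carries a unique chromaticity.
"""

from pathlib import Path

import mripad as mp

spec = mp.ColorMapSpec()
out = Path("scratch_examples")
out.mkdir(exist_ok=True)
mp.colormap.save_map_png(spec, out / "map.png", dots_per_mm=4.0)

raster = mp.render_map_raster(spec, dots_per_mm=4.0)
print(f"map raster: {raster.shape[0]} x {raster.shape[1]} px "
      f"({spec.side_mm:.0f} mm frame at 4 px/mm)")
center = tuple(int(v) for v in mp.ideal_color_at(spec, [100, 100]))
print(f"center color (RGB bytes): {center}")
print(f"spec hash: {mp.spec_hash(spec)}  (chains calibration and LUT files)")
# The center is neutral gray: equal pigment load from all three gradients.
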