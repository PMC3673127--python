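"""Simulate writing the letter "H" and decode it into strokes and metrics."""

from pathlib import Path

import mripad as mp

spec = mp.ColorMapSpec()
model = mp.SensorModel()
table = mp.calibrate_simulated(spec, model, seed=1)
fwd = mp.interpolate_forward(table, 32)
fwd.meta["spec_hash"] = table.meta["spec_hash"]
lut = mp.build_lut(fwd)

fixture = mp.make_fixture_scripts(spec)["H"]
stream = mp.simulate_stream(spec, model, fixture.script, seed=7)
result = mp.decode_stream(stream, lut)

resp = result.responses[0]
m = resp.metrics
print(f"{len(stream)} samples -> {len(result.responses)} response, "
      f"{m.stroke_count} strokes, {m.liftoff_count} lift-offs")
for i, (length, speed) in enumerate(zip(m.path_lengths_mm, m.mean_speeds_mm_s)):
    print(f"  stroke {i}: {length:6.1f} mm at {speed:5.1f} mm/s mean")
print(f"pen-down time {m.pen_down_time_s:.2f} s, "
      f"hesitations: {len(m.hesitations)}")

out = Path("scratch_examples")
out.mkdir(exist_ok=True)
mp.decoder.save_response_images(resp, lut, out / "letter_H")
print(f"letter raster saved to {out}/letter_H.png (+ .jpg)")
# Stroke order and speeds are the dynamics a scoring analysis consumes.
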