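"""Correct uneven illumination on a synthetic H&E phantom.

Builds a phantom degraded by a planar lightness loss, auto-selects four
white source points (one per quadrant), estimates the deficit mask and
restores it at full strength (factor 5), then scores the result against
the known clean image.
"""

import koehler
from koehler.imgio import from_uint8, to_uint8

phantom = koehler.generate_phantom(seed=42)

before = koehler.measure_recovery(phantom, phantom.degraded)
corrected, mask, points = koehler.correct_rgb(phantom.degraded, factor=5)
after = koehler.measure_recovery(phantom, from_uint8(to_uint8(corrected)))

print("auto-selected source points (x, y, L*):")
for p in points.points:
    print(f"  ({p.x:6.1f}, {p.y:6.1f})  L* = {p.lstar:6.2f}")
print(f"estimated deficit mask range: {mask.min():.2f} .. {mask.max():.2f} L*")
print(f"white-area L* RMSE:  {before.white_rmse:.3f} -> {after.white_rmse:.3f}")
print(f"overall    L* RMSE:  {before.overall_rmse:.3f} -> {after.overall_rmse:.3f}")
print(f"max |a*| change: {after.max_delta_a:.3f}, max |b*| change: {after.max_delta_b:.3f}")

# The RMSE lines show how far the lightness channel sits from the clean
# ground truth before and after correction; the deficit of ~9 L* units
# collapses to well under one unit.  The a*/b* deltas are quantization
# noise only: the correction never touches chromaticity.
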