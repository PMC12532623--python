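"""From a Hounsfield-unit raster to the standard 200x100 silhouette.

Builds a phantom axial slice (soft tissue, a bone plate, and an enclosed
air cavity standing in for the frontal sinus), thresholds it at 200 HU,
extracts the enclosed cavity inside a region of interest, and normalizes
it onto the 200x100 canvas.
"""

import numpy as np

from sinusid import HUSlice, ROI, preprocess_slice
from sinusid.preprocess import extract_sinus_silhouette, threshold_hu

# phantom: -600 HU background, 1200 HU bone plate, -950 HU cavity
values = np.full((80, 120), -600, dtype=np.int32)
values[10:70, 10:110] = 1200
yy, xx = np.mgrid[0:80, 0:120]
values[((xx - 60) / 35.0) ** 2 + ((yy - 40) / 18.0) ** 2 <= 1] = -950
hu = HUSlice(values=values)
roi = ROI(12, 12, 108, 68)

bone_map = threshold_hu(hu)                      # < 200 HU -> black (0)
cavity = extract_sinus_silhouette(bone_map, roi)  # largest enclosed black blob
sil = preprocess_slice(hu, roi)                   # full pipeline incl. canvas fit

print(f"slice {hu.values.shape[1]}x{hu.values.shape[0]} px, "
      f"{(bone_map == 0).sum()} sub-threshold px")
print(f"enclosed cavity: {(cavity == 0).sum()} px inside the ROI")
print(f"normalized silhouette: {sil.pixels.shape[1]}x{sil.pixels.shape[0]} canvas, "
      f"{sil.area()} sinus px")
print("\nThe cavity survives because it is sub-threshold air fully enclosed by")
print("bone; the ROI border rule discards air connected to the outside.")
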