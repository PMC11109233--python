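"""Extract the seven color-composition features from one drawing.

Builds a tiny drawing in memory (a red square with a blue stripe on a
white canvas), runs the HSV classification pipeline and prints the
feature vector.
"""

import numpy as np

from emodraw import RasterImage, extract_features

# 100x100 white canvas; rows 20-59 red, rows 60-79 blue
rgb = np.full((100, 100, 3), 255, dtype=np.uint8)
rgb[20:60, 20:80] = (230, 20, 20)     # red block: 40 x 60 px
rgb[60:80, 20:80] = (20, 40, 230)     # blue block: 20 x 60 px

fv = extract_features(RasterImage(rgb, "demo_anger"))

print(f"prominent color : {fv.prominent_color}")
for color, pct in fv.color_pct.items():
    if pct:
        print(f"  {color:<7s} share : {pct:6.2f} %")
print(f"colors used     : {fv.n_colors}")
print(f"saturation      : {fv.saturation_pct:6.2f} %")
print(f"brightness      : {fv.brightness_pct:6.2f} %")
print(f"color fill      : {fv.color_fill_pct:6.2f} %")
print(f"image coverage  : {fv.image_coverage_pct:6.2f} %")

# The red block holds 2400 of the 3600 drawn pixels (66.67 %), the blue
# block the rest; fill is 3600/10000 = 36 % of the canvas, and coverage
# equals fill because the drawing has no enclosed blank holes.
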