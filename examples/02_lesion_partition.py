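"""Partition a lesion mask into concentric regions plus surrounding parenchyma.

The city-block distance transform assigns each lesion pixel an integer
layer (distance to the nearest background pixel); layers are grouped into
s concentric regions from the rim inward, and the 2-pixel-margin box
around the lesion supplies the parenchyma region s+1.
"""

import numpy as np

from lesionbow.partition import cityblock_distance_transform, label_regions, partition_layers

yy, xx = np.mgrid[0:19, 0:19]
mask = ((np.abs(yy - 9) + np.abs(xx - 9)) <= 7).astype(np.uint8)  # diamond lesion

dist = cityblock_distance_transform(mask)
L = dist.max()
part = partition_layers(L, s=3)
print(f"lesion has L = {L} distance layers; p = {part.p}, q = {part.q}")
print(f"layer ranges outer->inner: {part.ranges}")
print("(the innermost region absorbs the remainder: p, p, p+q layers)")

labels = label_regions(mask, s=3)
for region in (1, 2, 3, 4):
    name = f"region {region}" if region <= 3 else "parenchyma"
    print(f"{name:>10}: {(labels == region).sum():3d} pixels")

print("\nlabel map (0 = outside, 1..3 = lesion outer->inner, 4 = parenchyma):")
for row in labels[2:-2, 2:-2]:
    print(" ".join(str(v) for v in row))
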