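"""Extract the 93-feature low-level bank from one lesion ROI.

5 intensity + 16 GLCM + 48 Gabor + 12 wavelet-texture + 12 shape values;
this is the classical comparison baseline for the regional BoW features.
"""

import tempfile

import numpy as np

import lesionbow as lb

out = tempfile.mkdtemp(prefix="lesionbow-lowlevel-")
manifest = lb.generate_dataset(lb.PhantomParams(seed=1, n_patients_per_class=1), out)
rec = lb.read_manifest(manifest)[0]
image = lb.load_image(rec)
roi = lb.build_roi(image, lb.load_mask(rec, image), s=3, label=rec.label)

block = lb.all_lowlevel(roi)
print(f"{rec.label} lesion, {rec.phase} phase, crop {roi.crop.shape}")
for name, values in [("intensity", block.intensity), ("glcm", block.glcm),
                     ("gabor", block.gabor), ("wavelet", block.wavelet),
                     ("shape", block.shape)]:
    print(f"  {name:<10} {len(values):2d} values, range "
          f"[{values.min():9.3f}, {values.max():9.3f}]")
print(f"total: {block.concat.shape[0]} features, all finite: "
      f"{bool(np.isfinite(block.concat).all())}")

names = lb.feature_names()
print("\nfirst five (gray-level histogram statistics of the lesion):")
for name, value in zip(names[:5], block.intensity):
    print(f"  {name:<22} {value:8.3f}")
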