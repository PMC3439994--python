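"""Generate a synthetic triple-phase liver-lesion dataset and inspect it.

Each class follows its clinical enhancement pattern: HCC is brighter than
parenchyma in AP and darker afterwards, hemangiomas show a bright rim
filling in toward the center, cysts stay uniformly dark.
"""

import tempfile

import numpy as np

import lesionbow as lb

out = tempfile.mkdtemp(prefix="lesionbow-phantoms-")
manifest = lb.generate_dataset(lb.PhantomParams(seed=1), out)
records = lb.read_manifest(manifest)
patients = {r.patient_id for r in records}
print(f"wrote {manifest}: {len(records)} images from {len(patients)} patients")

print("\nmean lesion - parenchyma gray difference per class and phase:")
print("(positive = lesion brighter than surrounding liver)")
for label in ("HCC", "hemangioma", "cyst"):
    row = []
    for phase in ("AP", "PVP", "DP"):
        diffs = []
        for rec in records:
            if rec.label != label or rec.phase != phase:
                continue
            image = lb.load_image(rec)
            mask = lb.load_mask(rec, image).pixels.astype(bool)
            diffs.append(image.pixels[mask].mean() - image.pixels[~mask].mean())
        row.append(f"{phase}: {np.mean(diffs):+7.1f}")
    print(f"  {label:<12} " + "  ".join(row))
print("\nHCC flips sign after AP ('fast in and fast out'); the cyst stays")
print("dark in every phase; the hemangioma's mean rises as its core fills in.")
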