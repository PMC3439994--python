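"""Build a visual codebook and regional bag-of-visual-words features.

Dense 7x7 intensity patches from every labeled ROI pixel are filtered
(background-dominated windows dropped), clustered into K-means visual
words, and histogrammed per region; the concatenated histograms are the
lesion descriptor. Patient-level features average image features over a
phase subset.
"""

import tempfile

import numpy as np

import lesionbow as lb

out = tempfile.mkdtemp(prefix="lesionbow-bow-")
manifest = lb.generate_dataset(lb.PhantomParams(seed=1), out)
records = lb.read_manifest(manifest)

# pool filtered patch descriptors from every image, then cluster
pool = []
rois = []
for rec in records:
    image = lb.load_image(rec)
    roi = lb.build_roi(image, lb.load_mask(rec, image), s=3, label=rec.label)
    rois.append(roi)
    pool.append(lb.filter_patches(lb.extract_patches(roi)).descriptors)
descriptors = np.concatenate(pool)
codebook = lb.train_codebook(descriptors, n_words=64, seed=1)
print(f"{descriptors.shape[0]} patch descriptors -> {codebook.n_words}-word codebook")

feat = lb.bow_feature(rois[0], codebook)
print(f"one ROI -> regional BoW of dimension {feat.dimension} "
      f"(= (s+1) x N = 4 x 64)")
print(f"vector mass {feat.values.sum():.1f} = number of nonempty regions "
      "(each nonempty region histogram is a probability vector)")

pid = records[0].patient_id
image_feats = [lb.bow_feature(r, codebook) for r in rois if r.patient_id == pid]
for subset in (("PVP",), ("AP", "PVP"), ("AP", "PVP", "DP")):
    pf = lb.patient_feature(image_feats, subset)
    n = sum(1 for f in image_feats if f.phase in subset)
    print(f"patient {pid}, phases {'+'.join(subset)}: mean of {n} image features")
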