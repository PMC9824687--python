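"""Score a simple patch classifier with the confusion-matrix machinery.

A nearest-threshold predictor calls a patch abnormal when its mean
intensity exceeds the top multilevel-Otsu threshold of the breast; the
report shows overall accuracy (TP+TN)/(TP+TN+FP+FN), its complement
error, and per-class precision/recall/f1/support.
"""

from mammoprep import (
    ClassLabel,
    PhantomSpec,
    build_confusion,
    compute_histogram,
    extract_silhouette,
    extract_tiles,
    generate_phantom,
    otsu_multithreshold,
    per_class_report,
)

true, pred = [], []
for seed in range(5):
    res = generate_phantom(PhantomSpec(seed=seed))
    mask = extract_silhouette(res.image)
    tiles = extract_tiles(res.image, mask, res.lesion_truth,
                          ClassLabel.MALIGNANT_MASS, lesion_frac=0.1)
    top = otsu_multithreshold(compute_histogram(res.image, 256, mask), 3).values[-1]
    for t in tiles.all_tiles():
        true.append(t.label)
        pred.append(ClassLabel.MALIGNANT_MASS if t.pixels.mean() > top
                    else ClassLabel.HEALTHY)

cm = build_confusion(true, pred, [ClassLabel.HEALTHY, ClassLabel.MALIGNANT_MASS])
print("confusion matrix (rows = truth, cols = prediction):")
print(cm.counts)
print(per_class_report(cm).round(3).to_string())
# The __overall__ row is the fraction of correctly labelled patches;
# __error__ is its exact complement.
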