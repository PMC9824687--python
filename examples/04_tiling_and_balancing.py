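"""Cut an enhanced phantom into labelled 32x32 patches and balance them.

Patches overlapping the ground-truth lesion mask get the lesion class;
the rest of the breast becomes healthy tissue.  Balancing undersamples
every class to the smallest one so a downstream classifier sees equal
class frequencies.
"""

from mammoprep import (
    CLAHE_PRESETS,
    ClassLabel,
    PhantomSpec,
    balance_classes,
    crop_breast,
    enhance_clahe,
    extract_silhouette,
    extract_tiles,
    generate_phantom,
)

res = generate_phantom(PhantomSpec(seed=7))
mask = extract_silhouette(res.image)
enhanced = enhance_clahe(crop_breast(res.image, mask), CLAHE_PRESETS["test6"])

tiles = extract_tiles(enhanced, mask, res.lesion_truth,
                      ClassLabel.MALIGNANT_MASS, lesion_frac=0.1)
print("tile counts:", {k.value: v for k, v in tiles.counts.items()})

balanced = balance_classes(tiles, seed=7)
print("after balancing:", {k.value: v for k, v in balanced.counts.items()})
# Every class now holds the same number of patches (the smallest class
# count); the selection is reproducible for a fixed seed.
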