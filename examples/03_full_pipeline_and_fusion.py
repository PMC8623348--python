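"""The complete decompose - segment - fuse pipeline on a noisy phantom.

Runs all four method variants (plain Otsu, interval iteration, interval
iteration on the base layer, and the fused pipeline) and reports the
uniformity measure of each, scored against the noise-free reference.
"""

import numpy as np

from iimtseg import (
    PhantomSpec,
    add_gaussian_noise,
    generate_phantom,
    segment,
    uniformity,
)

image, truth = generate_phantom(
    PhantomSpec(height=160, width=160, class_means=(30, 60, 95, 130, 170), seed=3)
)
noisy = add_gaussian_noise(image, variance=0.001, seed=11)

print(f"{'method':>10}  {'U (vs clean)':>12}  {'ME vs truth':>11}")
for method in ("otsu", "iimt", "hl-iimt", "proposed"):
    result = segment(noisy, k=4, method=method, truth=truth)
    u = uniformity(image, result.labels, k=4)
    print(f"{method:>10}  {u:12.4f}  {result.report.misclassification_error:11.4f}")
# "proposed" fuses the original-image and base-layer segmentations; its
# higher uniformity and lower misclassification error quantify how many
# noise-flipped pixels the similarity vote corrected.
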