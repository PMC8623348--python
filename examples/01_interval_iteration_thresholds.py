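"""Interval-iteration thresholding on a noisy multimodal phantom.

Builds a four-class phantom, adds acquisition-style noise, and compares
the thresholds found by global multilevel Otsu with those refined by
interval iteration, printing the per-iteration trace of each threshold.
"""

import numpy as np

from iimtseg import (
    IimtConfig,
    PhantomSpec,
    add_gaussian_noise,
    apply_thresholds,
    compute_histogram,
    generate_phantom,
    otsu_multilevel,
    run_iimt,
)

image, truth = generate_phantom(
    PhantomSpec(height=128, width=128, class_means=(25, 95, 165, 235), seed=1)
)
noisy = add_gaussian_noise(image, variance=0.001, seed=42)
hist = compute_histogram(noisy)

t_otsu = otsu_multilevel(hist, 3)
t_iimt, state = run_iimt(hist, IimtConfig(k=3))

print("global Otsu thresholds:  ", t_otsu.tolist())
print("interval-iteration final:", t_iimt.tolist())
for i, track in enumerate(state.tracks):
    print(f"  threshold {i + 1}: trace {track.history} "
          f"(converged in interval [{track.lower:.1f}, {track.upper:.1f}])")

labels = apply_thresholds(noisy, t_iimt)
agreement = (labels == truth).mean()
print(f"pixel agreement with ground truth: {agreement:.4f}")
# The traces show each threshold settling inside its inter-class interval;
# agreement near 1 means the thresholds fall in the true inter-class gaps.
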