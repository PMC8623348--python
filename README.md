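# iimtseg

Multilevel thresholding segmentation for grayscale (brain MR) images,
built around **interval-iteration multilevel thresholding (IIMT)**: instead
of accepting the thresholds of a single global Otsu search, each threshold
is iteratively re-estimated by single-threshold Otsu inside a shrinking
gray-level interval bounded by the class means of the previous iteration.
The full pipeline combines three components:

1. **Hybrid L1–L0 layer decomposition** — the image `I` is split into a
   smooth base layer `I_B` and a detail layer `I_D = I − I_B` by minimizing

   ```
   Σ (I_D)²  +  λ₁ Σ |∂ₖ I_B|  +  λ₂ Σ F(∂ₖ I_D),     k ∈ {H, V}
   ```

   (`F` the nonzero indicator), solved by an augmented-Lagrangian / ADMM
   scheme with an exact Fourier-domain quadratic step. The L1 prior keeps
   strong edges while flattening noise; the L0 prior keeps the detail
   layer's edges sparse.

2. **IIMT** on both the original image and its base layer. Global Otsu
   maximizes the between-class variance
   `σ_B² = Σᵢ ωᵢ (μᵢ − μ_T)²` over K strictly increasing integer
   thresholds (found here by an exact dynamic program); interval iteration
   then refines each threshold inside `[μᵢ, μᵢ₊₁]` until it stops moving
   (stopping constant δ).

3. **Similarity-weighted fusion** of the two label maps: pixels on which
   the maps agree keep their label; each disagreeing pixel is re-voted by
   its in-radius agreeing neighbors, weighted by
   `SIM(p,q) = exp(−(‖p−q‖²/2α² + |I(p)−I(q)|²/2β²))`.

Quality is measured by the uniformity measure `U`, misclassification error
`ME`, Hausdorff distance `H` and Jaccard index `J`. A synthetic phantom
generator (concentric brain-like shells with known ground truth, optional
Gaussian noise `N(0, σ²)` on the [0,1] intensity scale) makes every stage
testable without any image downloads.

## Worked example

```python
import numpy as np
from iimtseg import PhantomSpec, generate_phantom, add_gaussian_noise, segment, uniformity

image, truth = generate_phantom(
    PhantomSpec(height=160, width=160, class_means=(30, 60, 95, 130, 170), seed=3)
)
noisy = add_gaussian_noise(image, variance=0.001, seed=100)

plain = segment(noisy, k=4, method="otsu")
full = segment(noisy, k=4, method="proposed", truth=truth)

print("Otsu thresholds:", plain.thresholds_original.tolist())
print("IIMT thresholds:", full.thresholds_original.tolist())
print("base-layer thresholds:", full.thresholds_base.tolist())
print("U(otsu)     =", round(uniformity(image, plain.labels, k=4), 4))
print("U(proposed) =", round(uniformity(image, full.labels, k=4), 4))
print("ME =", round(full.report.misclassification_error, 4),
      " J =", round(full.report.jaccard, 4))
```

Output:

```
Otsu thresholds: [44, 77, 112, 149]
IIMT thresholds: [44, 77, 112, 149]
base-layer thresholds: [43, 72, 102, 132]
U(otsu)     = 0.9858
U(proposed) = 0.9952
ME = 0.0046  J = 0.9758
```

The four thresholds of each path separate the five phantom classes; the
uniformity measure is scored against the noise-free reference image, so
the gap between 0.9858 and 0.9952 quantifies how many noise-flipped pixels
the base-layer agreement and the similarity vote corrected. `ME` near zero
and `J` near one say the fused map almost coincides with the ground truth.

The same pipeline is available from the shell:

```bash
iimtseg phantom --means 20,90,160,230 --out phantom.png --labels-out truth.png
iimtseg segment phantom.png --k 3 --truth truth.png --out labels.png --report report.json
iimtseg metrics phantom.png labels.png --truth truth.png --k 3
```

Short narrative scripts, one per capability, live in `examples/`.

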