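"""Hybrid L1-L0 decomposition of a noisy phantom.

Splits a noisy image into a smooth base layer and a residual detail
layer, then quantifies the smoothing (mean |Laplacian|) and the exactness
of the reconstruction.
"""

import numpy as np
from scipy.ndimage import laplace

from iimtseg import (
    PhantomSpec,
    add_gaussian_noise,
    generate_phantom,
    hybrid_l1_l0_decompose,
)

image, truth = generate_phantom(
    PhantomSpec(height=128, width=128, class_means=(20, 90, 160, 230), seed=2)
)
noisy = add_gaussian_noise(image, variance=0.001, seed=7)

layers = hybrid_l1_l0_decompose(noisy)
base8 = layers.base_as_gray()

rough_in = np.abs(laplace(noisy / 255.0)).mean()
rough_base = np.abs(laplace(layers.base)).mean()
recon = np.abs(layers.base + layers.detail - noisy / 255.0).max()

print(f"mean |Laplacian| input: {rough_in:.4f}  base: {rough_base:.4f} "
      f"(ratio {rough_base / rough_in:.2f})")
print(f"max |base + detail - input| = {recon:.2e}")
for c in range(4):
    print(f"  class {c}: input mean {noisy[truth == c].mean():6.1f}  "
          f"base mean {base8[truth == c].mean():6.1f} gray levels")
# The base layer is markedly smoother (ratio well below 1) while the
# class-mean structure survives, and base + detail reproduces the input
# to machine precision.
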