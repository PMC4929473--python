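"""Masked histogram entropy as a background-robust contrast measure.

Computes Shannon entropy of the intensity histogram inside the detail
mask (pixels whose locally averaged intensity is in the top 20%) and
shows why the mask matters: surrounding the same content with a large
dark border barely moves the masked entropy, while the plain histogram
entropy collapses toward the background spike.
"""

import numpy as np

from iqrank import GrayImage, compute_detail_mask, masked_histogram, shannon_entropy
from iqrank.spatial_measures import DetailMask

rng = np.random.default_rng(0)
content = rng.uniform(20, 255, (96, 96))
plain = GrayImage(content)
bordered = GrayImage(np.pad(content, 48, constant_values=1.0))  # 4x area, mostly dark


def entropy(img, use_mask):
    if use_mask:
        mask = compute_detail_mask(img, filter_radius=8)
    else:
        mask = DetailMask(np.ones_like(img.pixels, dtype=bool))
    return shannon_entropy(masked_histogram(img, mask, n_bins=64))


for label, use_mask in (("unmasked", False), ("masked", True)):
    e_plain = entropy(plain, use_mask)
    e_border = entropy(bordered, use_mask)
    print(f"{label:9s} entropy: content only {e_plain:.3f} bits, "
          f"with dark border {e_border:.3f} bits  (shift {abs(e_plain - e_border):.3f})")
# The unmasked entropy drops by several bits once background dominates the
# histogram; the masked entropy stays close to the content-only value, so
# images with different amounts of empty field stay comparable.
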