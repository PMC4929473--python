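"""Power-spectrum tail statistics respond oppositely to blur and noise.

Computes fMean / fSTD / MeanBin at the 40% frequency threshold for a
sharp filament image, a blurred copy, and a noisy copy.  Blur attenuates
the tail (lower values); noise inflates it (higher values) - which is
why the inverse measures (invSTD etc.) are used when noise, rather than
blur, is the distortion of interest.
"""

import numpy as np

from iqrank import (
    GrayImage,
    gaussian_blur,
    make_base_image,
    power_spectrum_2d,
    reduce_summed,
    tail_stats,
)

base = make_base_image("filaments", (128, 128), seed=3)
blurred = gaussian_blur(base, 2.0)
rng = np.random.default_rng(1)
noisy = GrayImage(np.clip(base.pixels + rng.normal(0, 8, base.pixels.shape), 0, None))

print(f"{'image':10s} {'fMean':>10s} {'fSTD':>10s} {'MeanBin':>10s}")
for label, img in (("sharp", base), ("blurred", blurred), ("noisy", noisy)):
    s = tail_stats(reduce_summed(power_spectrum_2d(img)), threshold=0.40)
    print(f"{label:10s} {s.fMean:10.2f} {s.fSTD:10.2f} {s.MeanBin:10.2f}")
# Expected pattern: blur collapses every tail measure by orders of
# magnitude, while added noise clearly raises fMean and MeanBin (fSTD
# moves less here because the filament base already carries mild noise).
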