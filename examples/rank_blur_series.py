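"""Rank a simulated through-focus series and recover the blur order.

Generates a bead image blurred with Gaussian radii 0-29 (a simulated
autofocus series), ranks it with the spectral tail measures at the 2%
threshold, and shows that the ranking recovers the true radius order.
"""

import tempfile
from pathlib import Path

import pandas as pd

from iqrank import BlurSeriesSpec, make_blur_series, normalize_table, rank_order
from iqrank.pipeline import MeasureConfig, measure_dataset

with tempfile.TemporaryDirectory() as tmp:
    spec = BlurSeriesSpec(
        "beads", tuple(float(r) for r in range(30)), seed=7, image_size=(128, 128)
    )
    make_blur_series(spec, tmp)
    truth = pd.read_csv(Path(tmp) / "ground_truth.csv").set_index("image_id")

    # 2% threshold: maximum blur-detection dynamic range (autofocus regime)
    records = measure_dataset(tmp, MeasureConfig(threshold=0.02, mask_radius=40))
    table = normalize_table(records)

    ranked = rank_order(table, "fMean")
    radii_in_rank_order = [float(truth.loc[image_id, "radius"]) for image_id, _ in ranked]
    print("rank ->  radius   fMean (normalized)")
    for pos, (image_id, score) in enumerate(ranked[:5], 1):
        print(f"{pos:4d} -> {truth.loc[image_id, 'radius']:6.1f}   {score:.6f}")
    print(" ...")
    print("radius sequence along the ranking:", radii_in_rank_order[:8], "...")
    print("ranking recovers the radius order:",
          radii_in_rank_order == sorted(radii_in_rank_order))
# The sharpest image ranks first and every extra unit of blur radius drops
# the image exactly one rank: the tail fMean is strictly monotone in blur.
# (fSTD and MeanBin behave the same until extreme blur, where the 8-bit
# TIFF quantization of the generated files limits their resolution.)
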