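"""Run the image-quality stack on a synthetic radiograph crop.

Bilateral filtering suppresses noise while preserving tooth edges;
histogram equalization stretches the contrast; the 3:7 HE:BF composite
is the variant that detects best downstream.
"""

import numpy as np

from implantpath import (
    BilateralParams,
    SceneSpec,
    bilateral_filter,
    blend,
    generate_scene,
    hist_equalize,
)

scene = generate_scene(SceneSpec.from_angles(80, 100, seed=7, noise_sigma=12.0))
img = scene.image

bf = bilateral_filter(img, BilateralParams(sigma_spatial=2.0, sigma_range=25.0))
he = hist_equalize(img)
composite = blend(he, bf, ratio_he=0.3)


def describe(name, arr):
    tooth = arr[img > 110].mean()
    backgr = arr[img <= 110].mean()
    print(f"{name:10s} std {arr.std():6.2f}   tooth-background contrast {tooth - backgr:6.1f}")


describe("original", img.astype(float))
describe("bilateral", bf.astype(float))
describe("equalized", he.astype(float))
describe("HE:BF 3:7", composite.astype(float))

# The bilateral pass lowers the noise (std within regions) while keeping
# the contrast; equalization stretches contrast; the composite trades
# between the two.
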