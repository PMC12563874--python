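from __future__ import annotations

import numpy as np
import pytest

from implantpath import (
    OrientedBox,
    ToothPair,
    derive_pathway,
    fit_teeth_from_image,
)
from implantpath.geometry import Line, canonicalize


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def random_line(rng: np.random.Generator) -> Line:
    while True:
        a, b, c = rng.normal(size=3)
        if np.hypot(a, b) > 1e-6:
            return canonicalize(a, b, c * 50.0)


def random_box(rng: np.random.Generator, span: float = 100.0) -> OrientedBox:
    return OrientedBox(
        cx=float(rng.uniform(-span, span)),
        cy=float(rng.uniform(-span, span)),
        w=float(rng.uniform(1.0, 40.0)),
        h=float(rng.uniform(1.0, 40.0)),
        theta=float(rng.uniform(0.0, 180.0)),
    )


def pathway_from_image(scene):
    """Scene image -> threshold/refit boxes -> derived pathway."""
    boxes = fit_teeth_from_image(
        scene.image,
        threshold=(scene.spec.background + scene.spec.tooth_level) / 2.0,
    )
    return derive_pathway(ToothPair(boxes[0], boxes[1]))
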