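"""Synthetic single-gap radiograph scenes with analytic ground truth.

Real panoramic radiographs of edentulous sites cannot ship with a test
suite, so this module fabricates the geometry that matters to the
pathway algorithm: two bright tooth-shaped objects with known long-axis
angles flanking a darker gap, on a noisy low-contrast background
(background 60, teeth 160 by default, with a mild per-scene contrast
jitter).  Teeth are drawn as rotated rounded rectangles with a slight
root taper — enough structure for oriented-box fitting without
pretending to be anatomy.

Each scene carries its exact oriented-box labels and the analytic
ground-truth pathway (the internal bisector of the gap-facing edge
lines), so every downstream stage can be checked end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .enhancement import round_half_up_u8
from .geometry import OrientedBox, Point, obb_corners
from .io_formats import AnnotationSet, LabelRecord, write_image, write_obb_labels
from .pathway import Pathway, ToothPair, derive_pathway

__all__ = ["ToothSpec", "SceneSpec", "Scene", "generate_scene", "generate_batch"]

ROOT_TAPER = 0.25  # root end narrows to (1 - ROOT_TAPER) of crown width


@dataclass(frozen=True)
class ToothSpec:
    """One synthetic tooth: center, extents and the *long-axis* direction
    angle in degrees (mod 180; 90 = vertical tooth, crown up)."""

    cx: float
    cy: float
    length: float = 90.0
    width: float = 34.0
    angle_deg: float = 90.0

    def box(self) -> OrientedBox:
        # OrientedBox theta is the w-side direction; the long axis runs
        # along h, i.e. at theta + 90
        return OrientedBox(
            self.cx, self.cy, self.width, self.length, (self.angle_deg - 90.0) % 180.0
        )


@dataclass(frozen=True)
class SceneSpec:
    """Scene parameters: image size, two teeth, intensity model, noise."""

    width: int = 224
    height: int = 160
    left: ToothSpec = ToothSpec(cx=75.0, cy=80.0)
    right: ToothSpec = ToothSpec(cx=149.0, cy=80.0)
    background: float = 60.0
    tooth_level: float = 160.0
    contrast_jitter: float = 0.10  # per-scene relative jitter of tooth level
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("image too small")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def from_angles(
        cls,
        angle_left: float,
        angle_right: float,
        gap: float = 40.0,
        seed: int = 0,
        noise_sigma: float = 5.0,
        **kwargs,
    ) -> "SceneSpec":
        """Symmetric layout: two teeth with the given long-axis angles,
        placed about the image center so the facing edges are roughly
        ``gap`` px apart at mid-height."""
        base = cls(seed=seed, noise_sigma=noise_sigma, **kwargs)
        cy = base.height / 2.0
        cx0 = base.width / 2.0
        w = base.left.width

        def offset(angle: float) -> float:
            s = abs(np.sin(np.radians(angle)))
            return gap / 2.0 + (w / 2.0) / max(s, 0.5)

        left = ToothSpec(cx0 - offset(angle_left), cy, angle_deg=angle_left % 180.0)
        right = ToothSpec(cx0 + offset(angle_right), cy, angle_deg=angle_right % 180.0)
        return replace(base, left=left, right=right)


@dataclass(frozen=True)
class Scene:
    image: np.ndarray
    annotations: AnnotationSet
    truth: Pathway
    spec: SceneSpec


def _tooth_mask(spec: ToothSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Rounded, root-tapered tooth silhouette inside the labeled box.

    Local coordinates: v along the long axis (root at +v, i.e. the
    larger-y end for near-vertical teeth), u across it.
    """
    a = np.radians(spec.angle_deg)
    ax, ay = np.cos(a), np.sin(a)
    dx, dy = X - spec.cx, Y - spec.cy
    v = dx * ax + dy * ay
    u = -dx * ay + dy * ax
    half_len = spec.length / 2.0
    vn = np.clip(v / half_len, -1.0, 1.0)
    halfwidth = (spec.width / 2.0) * (1.0 - ROOT_TAPER * np.clip(vn, 0.0, 1.0))
    cap = min(spec.width / 2.0, spec.length / 8.0)
    body = (np.abs(v) <= half_len - cap) & (np.abs(u) <= halfwidth)
    in_cap = (np.abs(v) > half_len - cap) & (np.abs(v) <= half_len)
    with np.errstate(invalid="ignore"):
        cap_frac = (np.abs(v) - (half_len - cap)) / cap
        cap_ok = in_cap & (
            np.abs(u) <= halfwidth * np.sqrt(np.clip(1.0 - cap_frac**2, 0.0, 1.0))
        )
    return body | cap_ok


def _check_disjoint(left: OrientedBox, right: OrientedBox) -> None:
    from shapely.geometry import Polygon

    if Polygon(obb_corners(left)).intersects(Polygon(obb_corners(right))):
        raise ValueError("tooth boxes overlap: invalid scene spec")


def generate_scene(spec: SceneSpec) -> Scene:
    """Render a scene; deterministic for a given seed.

    The emitted OBB labels are exactly the spec's tooth rectangles, and
    the emitted pathway is the internal bisector of their gap-facing edge
    lines (midline for parallel teeth).
    """
    lbox, rbox = spec.left.box(), spec.right.box()
    _check_disjoint(lbox, rbox)
    rng = np.random.default_rng(spec.seed)

    level = spec.tooth_level
    if spec.contrast_jitter > 0:
        level *= 1.0 + rng.uniform(-spec.contrast_jitter, spec.contrast_jitter)

    Y, X = np.mgrid[0 : spec.height, 0 : spec.width].astype(float)
    img = np.full((spec.height, spec.width), spec.background, dtype=float)
    mask = _tooth_mask(spec.left, X, Y) | _tooth_mask(spec.right, X, Y)
    img[mask] = level
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    image = round_half_up_u8(img)

    ann = AnnotationSet(
        image_id=f"scene_{spec.seed:08d}",
        records=[LabelRecord(0, lbox), LabelRecord(0, rbox)],
    )
    truth = derive_pathway(ToothPair(lbox, rbox))
    return Scene(image=image, annotations=ann, truth=truth, spec=spec)


def generate_batch(
    n: int,
    out_dir: str | Path,
    angle_range: tuple[float, float] = (70.0, 110.0),
    gap: float = 40.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> dict:
    """Write ``n`` scenes (PNG + OBB labels) and a manifest with the
    per-scene seeds, angles and ground-truth pathways.

    Angles for both teeth are sampled independently and uniformly from
    ``angle_range`` (long-axis direction, degrees).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "n": n, "angle_range": list(angle_range),
                      "gap": gap, "noise_sigma": noise_sigma, "scenes": []}
    for i in range(n):
        a_l = float(rng.uniform(*angle_range))
        a_r = float(rng.uniform(*angle_range))
        scene_seed = int(rng.integers(0, 2**31 - 1))
        spec = SceneSpec.from_angles(a_l, a_r, gap=gap, seed=scene_seed,
                                     noise_sigma=noise_sigma)
        scene = generate_scene(spec)
        stem = f"scene_{i:04d}"
        write_image(scene.image, out / f"{stem}.png")
        scene.annotations.image_id = stem
        write_obb_labels(scene.annotations, out / f"{stem}.txt",
                         (spec.width, spec.height))
        seg = scene.truth.segment
        manifest["scenes"].append(
            {
                "image": f"{stem}.png",
                "labels": f"{stem}.txt",
                "scene_seed": scene_seed,
                "angle_left": round(a_l, 6),
                "angle_right": round(a_r, 6),
                "truth_angle_deg": round(scene.truth.angle_deg, 6),
                "truth_line": {
                    "A": round(scene.truth.line.A, 6),
                    "B": round(scene.truth.line.B, 6),
                    "C": round(scene.truth.line.C, 6),
                },
                "truth_endpoints": [
                    [round(seg[0].x, 6), round(seg[0].y, 6)],
                    [round(seg[1].x, 6), round(seg[1].y, 6)],
                ],
                "image_size": [spec.width, spec.height],
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
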