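"""Independent reference implementations used only by the tests.

These deliberately avoid the package's production code paths: the
bilateral oracle is a naive per-pixel double loop with its own border
reflection, the IoU oracle is a hand-written Sutherland-Hodgman convex
clipper, and the internal-bisector direction oracle works directly on
direction vectors.
"""

from __future__ import annotations

import math

import numpy as np


def _reflect_index(i: int, n: int) -> int:
    """Mirror-without-edge-repeat boundary (…, 2, 1 | 0, 1, 2, … )."""
    if n == 1:
        return 0
    period = 2 * n - 2
    i = i % period
    return i if i < n else period - i


def brute_bilateral(img: np.ndarray, sigma_spatial: float, sigma_range: float,
                    radius: int) -> np.ndarray:
    """Direct discretization of the double-Gaussian weighted mean."""
    arr = np.asarray(img, dtype=float)
    h, w = arr.shape
    out = np.zeros_like(arr)
    for y in range(h):
        for x in range(w):
            center = arr[y, x]
            num = den = 0.0
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    v = arr[_reflect_index(y + dy, h), _reflect_index(x + dx, w)]
                    wgt = math.exp(
                        -(dx * dx + dy * dy) / (2.0 * sigma_spatial**2)
                    ) * math.exp(-((v - center) ** 2) / (2.0 * sigma_range**2))
                    num += wgt * v
                    den += wgt
            out[y, x] = num / den
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def windowed_gaussian_blur(img: np.ndarray, sigma: float, radius: int) -> np.ndarray:
    """Plain spatial-Gaussian windowed mean (the sigma_range -> inf limit)."""
    arr = np.asarray(img, dtype=float)
    h, w = arr.shape
    kernel = np.array(
        [
            [math.exp(-(dx * dx + dy * dy) / (2.0 * sigma**2))
             for dx in range(-radius, radius + 1)]
            for dy in range(-radius, radius + 1)
        ]
    )
    kernel /= kernel.sum()
    out = np.zeros_like(arr)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for ky, dy in enumerate(range(-radius, radius + 1)):
                for kx, dx in enumerate(range(-radius, radius + 1)):
                    acc += kernel[ky, kx] * arr[
                        _reflect_index(y + dy, h), _reflect_index(x + dx, w)
                    ]
            out[y, x] = acc
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# convex polygon clipping


def clip_polygon(subject: list[tuple[float, float]],
                 clipper: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Sutherland-Hodgman clipping of `subject` by convex `clipper`.

    The clipper must be in a consistent winding; inside-ness is taken
    from the sign of the clipper's own area.
    """
    area2 = 0.0
    for i in range(len(clipper)):
        x1, y1 = clipper[i]
        x2, y2 = clipper[(i + 1) % len(clipper)]
        area2 += x1 * y2 - x2 * y1
    orient = 1.0 if area2 >= 0 else -1.0

    output = list(subject)
    for i in range(len(clipper)):
        if not output:
            return []
        cp1 = clipper[i]
        cp2 = clipper[(i + 1) % len(clipper)]
        ex, ey = cp2[0] - cp1[0], cp2[1] - cp1[1]

        def inside(p):
            return orient * (ex * (p[1] - cp1[1]) - ey * (p[0] - cp1[0])) >= 0.0

        def intersection(a, b):
            dx, dy = b[0] - a[0], b[1] - a[1]
            denom = ex * dy - ey * dx
            t = (ey * (a[0] - cp1[0]) - ex * (a[1] - cp1[1])) / denom
            return (a[0] + t * dx, a[1] + t * dy)

        input_list, output = output, []
        s = input_list[-1]
        for p in input_list:
            if inside(p):
                if not inside(s):
                    output.append(intersection(s, p))
                output.append(p)
            elif inside(s):
                output.append(intersection(s, p))
            s = p
    return output


def shoelace_area(poly: list[tuple[float, float]]) -> float:
    if len(poly) < 3:
        return 0.0
    area2 = 0.0
    for i in range(len(poly)):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % len(poly)]
        area2 += x1 * y2 - x2 * y1
    return abs(area2) / 2.0


def iou_by_clipping(corners_a, corners_b) -> float:
    """Rotated-box IoU via polygon clipping, independent of shapely."""
    a = [(p[0], p[1]) for p in corners_a]
    b = [(p[0], p[1]) for p in corners_b]
    inter = shoelace_area(clip_polygon(a, b))
    if inter <= 0.0:
        return 0.0
    union = shoelace_area(a) + shoelace_area(b) - inter
    return inter / union


# ---------------------------------------------------------------------------
# direction arithmetic


def internal_direction_by_vectors(d1_deg: float, d2_deg: float) -> float:
    """Wedge-midpoint direction from unit vectors: pick representatives
    with non-negative dot product and normalize their sum."""
    u1 = (math.cos(math.radians(d1_deg)), math.sin(math.radians(d1_deg)))
    u2 = (math.cos(math.radians(d2_deg)), math.sin(math.radians(d2_deg)))
    if u1[0] * u2[0] + u1[1] * u2[1] < 0:
        u2 = (-u2[0], -u2[1])
    sx, sy = u1[0] + u2[0], u1[1] + u2[1]
    return math.degrees(math.atan2(sy, sx)) % 180.0
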