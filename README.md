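# implantpath

Implant-pathway derivation from oriented tooth bounding boxes on dental
panoramic radiographs (DPRs).

## The problem

Planning a single-tooth implant starts with a question a clinician
answers on a panoramic radiograph: *at what angle should the implant
enter the edentulous gap?*  The standard heuristic references the
angulation of the two adjacent teeth — the insertion direction should
split the corridor between them, staying clear of both roots.  This
package automates that step.  It consumes the oriented bounding boxes
(OBBs) an object detector emits for the two neighbours and produces the
recommended pathway geometrically; it also provides the image-
enhancement stack used upstream of detection, the evaluation metrics
for both detection quality and pathway agreement, the label-format I/O,
and a synthetic scene generator so the whole pipeline is testable
without clinical data or a trained detector.

It is a library first (`import implantpath`), with a thin `implantpath`
CLI for shell pipelines.

## The method

Each adjacent tooth is an oriented box `(cx, cy, w, h, θ)`.  Auxiliary
lines — by default the box edge lines facing the gap, each parallel to
its tooth's long axis — are written in implicit form and fed to the
angle-bisector equation

```
(A₁x + B₁y + C₁)/√(A₁²+B₁²) = ± (A₂x + B₂y + C₂)/√(A₂²+B₂²)
```

The ± branches give two perpendicular bisectors; the **internal** one —
the branch whose direction lies inside the wedge spanned by the two
tooth axes — is the implant pathway.  Its entry point is where it
crosses the crest segment joining the coronal corners of the gap.  For
perfectly parallel neighbours the pathway is the midline between the
auxiliary lines.  See `docs/methods.md` for conventions, edge cases and
the enhancement/evaluation details.

## Worked example

```python
from implantpath import OrientedBox, ToothPair, derive_pathway

# theta is the w-side direction: a tooth with its long axis at 80 deg
# has theta = 80 - 90 = 170 (mod 180)
left = OrientedBox(cx=62, cy=80, w=34, h=90, theta=170)   # long axis 80 deg
right = OrientedBox(cx=162, cy=80, w=34, h=90, theta=10)  # long axis 100 deg

pw = derive_pathway(ToothPair(left, right))
print(f"pathway angle: {pw.angle_deg:.3f} deg")
print(f"entry point:   ({pw.entry_point.x:.2f}, {pw.entry_point.y:.2f})")
```

prints

```
pathway angle: 90.000 deg
entry point:   (112.00, 32.73)
```

The two teeth tilt mirror-symmetrically (80° and 100°), so the internal
bisector is exactly vertical (90°), entering midway between them on the
crest segment.  `examples/` contains runnable scripts for each
capability: pathway derivation, image enhancement, the synthetic
end-to-end loop, detection metrics, and the full CLI pipeline
(`examples/05_cli_pipeline.sh`).

## CLI

```sh
implantpath synth --n 8 --seed 11 --out data/          # synthetic scenes
implantpath enhance --input data/ --out enhanced/      # BF + HE + 3:7 composite
implantpath pathway --labels data/ --out pathways/     # OBB labels -> pathway JSON
implantpath eval-angle --pred pathways/ --truth data/manifest.json --out report.json
implantpath overlay --image data/scene_0000.png --labels data/scene_0000.txt \
    --pathway pathways/scene_0000.json --out overlay.png
```

Label formats are the standard normalized text dialects (OBB:
`class x1 y1 x2 y2 x3 y3 x4 y4`; HBB: `class cx cy w h`); pathways and
reports are JSON with 6-decimal floats so repeated runs are
byte-identical.

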