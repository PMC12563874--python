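"""Derive an implant pathway from two oriented tooth boxes.

Two teeth flank a single-tooth gap, tilted mirror-symmetrically (long
axes at 80 and 100 degrees).  The recommended insertion direction is the
internal bisector of the gap-facing edge lines — here exactly vertical.
"""

from implantpath import OrientedBox, ToothPair, derive_pathway

# OrientedBox theta is the w-side direction: a tooth whose long axis
# points at 80 deg has theta = 80 - 90 = -10 = 170 (mod 180)
left = OrientedBox(cx=62, cy=80, w=34, h=90, theta=170)   # long axis 80 deg
right = OrientedBox(cx=162, cy=80, w=34, h=90, theta=10)  # long axis 100 deg

pathway = derive_pathway(ToothPair(left, right))

print(f"pathway angle:  {pathway.angle_deg:.3f} deg")
print(f"entry point:    ({pathway.entry_point.x:.2f}, {pathway.entry_point.y:.2f})")
print(f"implicit line:  {pathway.line.A:.6f}*x + {pathway.line.B:.6f}*y + {pathway.line.C:.6f} = 0")
print(f"parallel teeth: {pathway.parallel_fallback}")

# The angle is the insertion direction (90 = vertical, counter-clockwise
# from the image x-axis); the entry point is where the pathway crosses
# the crest segment joining the coronal corners of the gap.
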