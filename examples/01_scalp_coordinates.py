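"""Continuous proportional coordinates (CPC) on an analytic head.

Builds a spherical scalp with the four fiducials (nasion NZ, inion IZ,
pre-auricular AL/AR), maps CPC coordinates to scalp points and back, and
constructs a coil frame. The apex of a symmetric head must sit at
(p_nz, p_al) = (0.5, 0.5), and the 0-degree coil direction points backward.
"""

import numpy as np

from tmstarget import CPCCoordinate, coil_frame, cpc_forward, cpc_inverse, make_head
from tmstarget.synthetic import HeadSpec

head = make_head(HeadSpec(radius_mm=85.0, subdivisions=4))

apex = cpc_forward(head, CPCCoordinate(0.5, 0.5))
print(f"scalp point at CPC (0.5, 0.5): {np.round(apex, 1)} mm  (the vertex, Cz analog)")

c = CPCCoordinate(0.4, 0.65)
p = cpc_forward(head, c)
back = cpc_inverse(head, p)
print(f"CPC {c.p_nz:.2f}/{c.p_al:.2f} -> {np.round(p, 1)} mm -> "
      f"CPC {back.p_nz:.3f}/{back.p_al:.3f}  (round trip)")

frame = coil_frame(head, CPCCoordinate(0.5, 0.5), theta_deg=-45.0)
print(f"coil at the apex, handle at -45 deg (clockwise from outside):")
print(f"  outward normal {np.round(frame.normal, 3)}")
print(f"  0-deg direction {np.round(frame.zero_dir, 3)}  (posterior: toward IZ)")
print(f"  handle direction {np.round(frame.handle_dir, 3)}")
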