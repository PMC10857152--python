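"""Position-dependent frame transforms: FEM, HCM, REM.

Holographic content prepared from a reference scan (RAS, mm) has to be
re-oriented for the surgical position and rescaled to the virtual platform's
centimetre, left-handed frame; measurements reported by the platform travel
the reverse path before any metric can be computed.
"""

import numpy as np

from navphantom import Frame, Unit, apply_transform, make_fem, make_hcm, make_rem
from navphantom.frames import FiducialSet

point_mm = np.array([[100.0, 50.0, -20.0]])
fs = FiducialSet(point_mm, labels=(1,), frame=Frame.RICS, units=Unit.MM)

for position in ("supine", "prone", "left_lateral"):
    fem = make_fem(position)
    hcm = make_hcm()
    ivcs = apply_transform(fem, fs)
    vcs = apply_transform(hcm, ivcs)
    print(f"{position:13s} RICS {point_mm[0]} mm -> IVCS {ivcs.points[0]} cm "
          f"-> VCS {vcs.points[0]} cm")

# the reverse engineering matrix undoes the FEM exactly
rem = make_rem("prone")
back = apply_transform(rem, apply_transform(make_fem("prone"), fs))
print(f"\nREM(FEM(x)) round trip error: "
      f"{np.abs(back.points - point_mm).max():.2e} mm")
print("A supine FEM is a pure 0.1 scale (mm -> cm); prone adds a half-turn")
print("about the superior axis; the HCM flips the z-axis (handedness).")
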