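"""Build a printable wall shell and verify it by ray casting.

The lumen surface is offset outward by 1.0 mm into a closed solid wall (the
3D-printing variant of the model); wall thickness is then measured at 100
random surface points by casting rays through the wall.
"""

import numpy as np

from aortagen.meshgen import (export, generate_model, measure_wall_thickness,
                              shell)

model = generate_model("I")
walled = shell(model.mesh, thickness=1.0)
export(walled, "output/aorta_type_i_shell.stl")

th_mm = measure_wall_thickness(walled, n_samples=100) * 10.0
print(f"shell watertight: {walled.is_watertight}")
print(f"wall thickness: mean {th_mm.mean():.3f} mm, "
      f"range [{th_mm.min():.3f}, {th_mm.max():.3f}] mm over {len(th_mm)} rays")
print("a mean within 1.0 +/- 0.1 mm confirms the offset wall is printable at"
      "\nthe tolerance of stereolithography printers.")
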