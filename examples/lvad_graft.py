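"""Graft an LVAD outflow cannula into the ascending aorta.

A 16 mm cannula is stitched into the mid-ascending aorta at 45 degrees with
a 15-diameter inflow development extension, as used for flow studies.  The
script prints the recovered cannula dimensions and the inflow conditions
(bulk velocity and Reynolds number) for device flow rates of 5 and 9 L/min.
"""

import numpy as np

from aortagen.hemo import FlowCondition, bulk_velocity, reynolds
from aortagen.meshgen import GraftSpec, export, generate_model

spec = GraftSpec()  # 16 mm, mid-ascending, 45 deg, 15-diameter extension
model = generate_model("I", graft=spec)
export(model.mesh, "output/aorta_type_i_grafted.stl")

br = [b for b in model.mesh.structure["branches"] if b["label"] == "cannula"][0]
pts = model.mesh.vertices[np.array(br["rings"][-1])]
c = pts.mean(axis=0)
d_mm = 20 * np.linalg.norm(pts - c, axis=1).mean()
ext_mm = 10 * np.linalg.norm(c - np.array(br["axis_origin"]))
print(f"cannula inlet diameter: {d_mm:.2f} mm (target {spec.cannula_diameter})")
print(f"inlet extension length: {ext_mm:.1f} mm "
      f"(target {spec.inlet_extension * spec.cannula_diameter:.0f})")

for q in (5.0, 9.0):
    cond = FlowCondition(Q=q, D=spec.cannula_diameter)
    print(f"Q = {q:.0f} L/min: bulk velocity {bulk_velocity(cond):.3f} m/s, "
          f"Re = {reynolds(cond):.0f}")
print("Re 1757 is transitional and 3163 mildly turbulent pipe flow; half the"
      "\n5 L/min bulk velocity (~0.2 m/s) is the usual jet isosurface level.")
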