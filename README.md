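# aortagen

Parametric generator of idealized human aorta geometries for *in vitro*
phantoms and *in silico* hemodynamics.

Patient-specific aortas are hard to compare across subjects and awkward to
manufacture and image; idealized models that carry the *population-average*
anatomy are the standard workaround in cardiovascular flow research, but
few exist and almost none are reproducible from printed dimensions.
`aortagen` builds such models from scratch: it ships a cohort-weighted
morphometry database of the healthy adult thoracic aorta (diameters, arch
height/width/bend radius, branch diameters/spacings/angles, coronary
diameters, arch-variant prevalences, transcribed per study with per-sex
sub-cohorts), and turns any parameter set into a watertight triangle mesh
ready for 3D printing or CFD pre-processing.

Who it is for: experimentalists needing a printable aortic phantom with
defensible dimensions, CFD practitioners needing a reference lumen with
labeled inlets/outlets, and device researchers studying LVAD (left
ventricular assist device) outflow-graft hemodynamics.

## The statistics and geometry at its core

Every dimension is the cohort-size-weighted mean over the literature,

```
x̄ = Σᵢ nᵢ xᵢ / Σᵢ nᵢ ,    N = Σᵢ nᵢ ,
```

with male/female sub-cohorts entering as independent terms and studies not
reporting a dimension excluded from that dimension's N.  Two arch variants
cover ~95% of the population: the Normal (Type I) arch with
brachiocephalic (BA), left common carotid (LCA) and left subclavian (LSA)
branches, and the Bovine (Type II) arch where BA and LCA share a common
trunk.

The lumen is a swept surface: a straight ascending segment of length L, an
arch whose parasagittal projection is a semi-ellipse spanning width W and
height H, a lateral bulge making its transverse (axial) projection exactly
a circular arc of radius R, and a descending limb tilted β₁ from vertical,
twisted β₂, with the whole arch plane rotated β₃.  Cross-sections are
circles interpolating the diameters D1 (ascending), D2 (arch) and D3
(mid-descending) with a monotone spline; cross-section orientation follows
rotation-minimizing frames.  Arch branches, a parametric three-sinus
aortic root with coronary stubs (diameters C1, C2), and an optional LVAD
cannula are stitched into the lattice, so the assembly is watertight and
genus 0 by construction.  A measurement suite recovers every input
dimension from the mesh alone and reports pass/fail at 2% length / 1°
angle tolerance.

## Worked example

```python
from aortagen.meshgen import export, generate_model

model = generate_model("I")             # Normal arch, weighted defaults
export(model.mesh, "aorta_type_i.stl")  # mm STL + .labels.json sidecar
print(model.validate())
```

prints (abridged):

```
symbol        target  measured     error     tol  pass
D1             3.170     3.170    0.0000   0.020  ok
D2             2.650     2.650    0.0000   0.020  ok
H              4.060     4.060    0.0000   0.020  ok
W              7.950     7.950    0.0000   0.020  ok
a              7.620     7.620    0.0000   0.020  ok
alpha1        84.800    84.890    0.0901   1.000  ok
C1             2.600     2.600    0.0000   0.020  ok
mesh: {'watertight': True, 'winding_consistent': True,
       'euler_characteristic': 2, 'genus': 0, ..., 'self_intersections': 0}
```

Each row is one generator input recovered purely from mesh geometry: the
ascending diameter D1 comes back at its 3.17 cm target, the arch
height/width exactly, the BA takeoff angle within 0.1°, and the mesh
block confirms the surface is a printable closed manifold.

The same pipeline is scriptable from the shell:

```
aortagen generate --type II --shell 1.0 --output bovine.stl
aortagen hemo --q 5 --d 16        # -> bulk velocity 0.4145 m/s, Re 1757
```

Short narrative scripts live in `examples/` (morphometry aggregation,
model generation, LVAD grafting, shelling and thickness verification).

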