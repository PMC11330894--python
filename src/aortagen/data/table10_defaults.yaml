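# Default parameter sets for the two idealized aorta models (summary table of
# cohort-weighted averages).  Lengths in cm, angles in degrees, coronary
# diameters C1/C2 in mm.  null marks symbols that do not apply to the variant.
type_i:
  arch_type: TypeI
  D1: 3.17
  D2: 2.65
  D3: 2.5
  root_diameter: 2.9
  proximal_descending_diameter: 2.4
  C1: 2.6
  C2: 3.5
  d1: 1.68
  d2: 3.44
  d3: null
  phi1: 1.47
  phi2: 0.97
  phi3: 1.14
  phib1: null
  phib2: null
  W: 7.95
  H: 4.06
  R: 12.2
  L: 2.6
  a: 7.62
  alpha1: 84.8
  alpha2: 73.3
  alpha3: 69.8
  alphab1: null
  alphab2: null
  beta1: 10.0
  beta2: 10.0
  beta3: 10.0
type_ii:
  arch_type: TypeII
  D1: 3.17
  D2: 2.65
  D3: 2.5
  root_diameter: 2.9
  proximal_descending_diameter: 2.4
  C1: 2.6
  C2: 3.5
  d1: null
  d2: null
  d3: 2.7
  phi1: null
  phi2: null
  phi3: null
  phib1: 2.18
  phib2: 1.07
  W: 7.95
  H: 4.06
  R: 12.2
  L: 2.6
  a: 7.62
  alpha1: null
  alpha2: null
  alpha3: null
  alphab1: 80.0
  alphab2: 65.0
  beta1: 10.0
  beta2: 10.0
  beta3: 10.0
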