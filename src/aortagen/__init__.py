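"""aortagen: parametric generator of idealized human aorta geometries.

Builds watertight surface meshes of the healthy adult aorta for in vitro
phantoms and in silico hemodynamics, from a cohort-weighted morphometry
database covering the two most prevalent arch variants (Normal / Type I and
Bovine / Type II), with optional wall shelling and LVAD outflow-cannula
grafting, plus an inverse-measurement QA suite.
"""

from .errors import (AortagenError, InfeasibleGeometryError, MeshError,
                     NoDataError, ParameterError)
from .params import AortaParameterSet, ArchType
from .morphometry import (aggregate_all, cumulative_n, default_parameters,
                          load_table, prevalences, weighted_mean)
from .centerline import (BranchStation, Centerline, FrameField, RadiusProfile,
                         branch_stations, build_centerline, radius_profile)
from .hemo import FlowCondition, bulk_velocity, reynolds

__version__ = "0.1.0"

__all__ = [
    "AortagenError", "InfeasibleGeometryError", "MeshError", "NoDataError",
    "ParameterError", "AortaParameterSet", "ArchType",
    "aggregate_all", "cumulative_n", "default_parameters", "load_table",
    "prevalences", "weighted_mean",
    "BranchStation", "Centerline", "FrameField", "RadiusProfile",
    "branch_stations", "build_centerline", "radius_profile",
    "FlowCondition", "bulk_velocity", "reynolds",
    "generate", "__version__",
]


def generate(params_or_type, resolution: float = 6.0, n_circumferential: int = 64,
             with_root: bool = True, shell_thickness: float | None = None,
             graft=None):
    """One-call model builder; see :func:`aortagen.meshgen.generate_model`."""
    from .meshgen import generate_model
    return generate_model(params_or_type, resolution=resolution,
                          n_circumferential=n_circumferential,
                          with_root=with_root, shell_thickness=shell_thickness,
                          graft=graft)
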