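"""Exception hierarchy for aortagen."""


class AortagenError(Exception):
    """Base class for all package errors."""


class NoDataError(AortagenError):
    """Raised when an aggregation column has no non-missing sub-cohorts."""


class ParameterError(AortagenError):
    """Invalid or inconsistent parameter set / configuration."""


class InfeasibleGeometryError(AortagenError):
    """The requested dimensions cannot be realized as a valid 3D shape.

    The message names the violated constraint (e.g. an arch bend radius too
    small to close the arch, or a branch station beyond the arch end).
    """


class MeshError(AortagenError):
    """Mesh construction, measurement, or validity failure."""
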