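"""Exception hierarchy.

Error classes map onto the failure modes a user can hit: malformed input
files, invalid graphs, degenerate geometry, inconsistent covers, infeasible
or failed optimisation, and runaway path enumeration.
"""


class FilacoverError(Exception):
    """Base class for all filacover errors."""


class GMLFormatError(FilacoverError):
    """A GML file is missing required attributes (weights, coordinates)."""


class GraphValidationError(FilacoverError):
    """A graph violates the data-model invariants (self-loop, bad weight...)."""


class GeometryError(FilacoverError):
    """Degenerate geometry: zero-length vector or coincident node positions."""


class CoverConsistencyError(FilacoverError):
    """A cover references edges absent from the graph, or label sets mismatch."""


class InfeasibleCoverError(FilacoverError):
    """An edge is covered by no candidate path, or the program is infeasible."""


class SolverError(FilacoverError):
    """The optimisation backend failed or did not converge."""


class PathEnumerationLimitError(FilacoverError):
    """Constrained path enumeration exceeded the configured safety cap."""
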