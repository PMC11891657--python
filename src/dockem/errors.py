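"""Exception hierarchy for dockem.

All library errors derive from :class:`DockemError` so callers can catch
one base class at the CLI boundary.
"""


class DockemError(Exception):
    """Base class for all dockem errors."""


class ParseError(DockemError):
    """A structure or map file could not be parsed."""


class TopologyError(DockemError):
    """Missing or inconsistent bond information."""


class ValidationError(DockemError):
    """A parsed object violates a structural invariant."""


class ParameterError(DockemError):
    """Missing or invalid force-field / model parameters."""


class GeometryError(DockemError):
    """Degenerate or out-of-bounds geometry."""


class LatticeMismatchError(GeometryError):
    """Two grids do not share a voxel lattice."""


class UnsupportedFormatError(DockemError):
    """A file is syntactically valid but uses an unsupported feature."""


class SiteError(DockemError):
    """Binding-site specification refers to missing residues."""


class AlignmentError(DockemError):
    """Protein-to-map alignment cannot proceed (e.g. flat map)."""


class SelectionError(DockemError):
    """Pose selection called with no candidates."""


class MappingError(DockemError):
    """No chemically valid atom correspondence exists."""


class MoveUnavailableError(DockemError):
    """The requested Monte Carlo move does not apply to this ligand."""


class FixtureSpecError(DockemError):
    """Infeasible synthetic-fixture specification."""
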