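"""Exception hierarchy for glycomem.

All package errors derive from :class:`GlycomemError` so callers can catch
one base class at CLI boundaries.
"""


class GlycomemError(Exception):
    """Base class for all glycomem errors."""


class ParseError(GlycomemError):
    """A file could not be parsed; the message names the offending line."""


class StructureError(GlycomemError):
    """Frames of a trajectory disagree on atom count or atom identity."""


class FormatError(GlycomemError):
    """A tabular input violates the declared dialect."""


class SelectionError(GlycomemError):
    """An atom selection is empty or ill-formed; the message names its label."""


class GeometryError(GlycomemError):
    """A geometric construction is impossible (e.g. an empty bilayer leaflet)."""


class DegeneracyError(GlycomemError):
    """An eigen- or superposition problem has no unique solution."""


class ValidationError(GlycomemError):
    """Input values violate a documented domain (e.g. pLDDT outside [0, 100])."""
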