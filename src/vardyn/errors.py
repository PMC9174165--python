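"""Exception hierarchy shared across the package.

All errors derive from :class:`VardynError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid input values.
"""


class VardynError(Exception):
    """Base class for all vardyn errors."""


class FormatError(VardynError, ValueError):
    """A file could not be parsed (bad fixed-column record, bad CSV cell)."""


class StructuralMismatchError(VardynError, ValueError):
    """Atom records differ between frames or between trajectories."""


class SelectionError(VardynError, ValueError):
    """A selection expression could not be parsed."""


class EmptySelectionError(SelectionError):
    """A well-formed selection matched no atoms.

    Raised explicitly because downstream statistics divide by atom counts.
    """


class EmptySliceError(VardynError, ValueError):
    """A time slice contains no frames."""


class DegenerateGeometryError(VardynError, ValueError):
    """Coordinates are too degenerate for the requested operation."""
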