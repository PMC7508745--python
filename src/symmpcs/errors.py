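"""Exception hierarchy.

Every error raised on bad scientific input derives from :class:`SymmpcsError`
so the CLI can map failures to distinct exit codes.
"""


class SymmpcsError(Exception):
    """Base class for all package errors."""

    category = "error"


class InvalidArgumentError(SymmpcsError):
    category = "invalid-argument"


class SingularityError(SymmpcsError):
    """Nucleus too close to the point-dipole center for Eq.-style evaluation."""

    category = "singularity"


class ParseError(SymmpcsError):
    category = "parse"


class LookupMissingError(SymmpcsError):
    category = "lookup"


class SymmetryDetectionError(SymmpcsError):
    category = "symmetry-detection"


class DegenerateGeometryError(SymmpcsError):
    category = "degenerate-geometry"


class UnderdeterminedError(SymmpcsError):
    """Fewer data points than free parameters."""

    category = "underdetermined"
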