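"""Exception hierarchy for maskfit."""


class MaskfitError(Exception):
    """Base class for all maskfit errors."""


class MeshFormatError(MaskfitError):
    """A mesh file could not be parsed as the named format."""


class GeometryError(MaskfitError):
    """Degenerate or inconsistent geometry (zero-area triangle, duplicate points, ...)."""


class ParameterError(MaskfitError):
    """Invalid user-supplied parameter."""


class RankError(MaskfitError):
    """A system matrix is singular (usually missing boundary conditions)."""


class ContactError(MaskfitError):
    """No admissible contact state (e.g. no positive-gap pairs at this push depth)."""


class CoverageError(MaskfitError):
    """A sweep candidate touches face vertices outside the condensed master set."""
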