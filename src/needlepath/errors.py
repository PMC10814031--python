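"""Exception hierarchy for the planner."""


class NeedlePathError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeedlePathError):
    """Invalid run configuration, role binding, or phantom specification."""


class FormatError(NeedlePathError):
    """Unsupported or malformed volume file."""


class GeometryError(NeedlePathError):
    """Degenerate or out-of-bounds geometric query."""


class EmptyStructureError(NeedlePathError):
    """A required anatomical structure has no voxels."""


class VerificationError(NeedlePathError):
    """Plan and scene do not belong together."""
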