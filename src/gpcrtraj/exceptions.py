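"""Exception hierarchy. Every error raised by the package derives from GPCRTrajError."""


class GPCRTrajError(Exception):
    """Base class for all package errors."""


class PDBParseError(GPCRTrajError):
    """A structure file could not be parsed; the message names the offending record."""


class IntegrityError(GPCRTrajError):
    """A container invariant is violated (duplicate atoms, frame atom-count mismatch...)."""


class SelectionError(GPCRTrajError):
    """An atom selection is empty or references atoms that do not exist."""


class LookupErrorBW(GPCRTrajError, KeyError):
    """A Ballesteros-Weinstein code cannot be resolved against the residue map."""


class GeometryError(GPCRTrajError):
    """A geometric operation received degenerate input (too few atoms, zero vector...)."""


class ParameterError(GPCRTrajError, ValueError):
    """An argument is outside its documented domain."""


class ConfigurationError(GPCRTrajError):
    """A config bundle is missing a required entry."""


class ScriptError(GPCRTrajError):
    """A synthetic scenario script is internally inconsistent."""
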