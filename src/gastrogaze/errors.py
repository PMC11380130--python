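"""Exception hierarchy for gastrogaze."""


class GastrogazeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GastrogazeError, ValueError):
    """Invalid simulation or analysis configuration."""


class FormatError(GastrogazeError, ValueError):
    """Malformed or invariant-violating on-disk artefact."""


class LayoutError(FormatError):
    """Invalid area-of-interest layout (overlapping or off-screen spans)."""


class InputError(GastrogazeError, ValueError):
    """Invalid in-memory input to an analysis operation."""
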