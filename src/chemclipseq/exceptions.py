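"""Exception hierarchy for the chemclipseq pipeline."""


class ChemClipError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ChemClipError):
    """Invalid configuration (bad ranges, out-of-bounds intervals, ...)."""


class ParseError(ChemClipError):
    """Malformed input file; message names the offending line where possible."""


class FitError(ChemClipError):
    """Null-model fitting failed (too few sites, zero dispersion)."""
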