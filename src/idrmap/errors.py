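"""Exception types shared across the pipeline stages."""


class IdrmapError(Exception):
    """Base class for all idrmap errors."""


class InvalidInputError(IdrmapError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(IdrmapError, ValueError):
    """A file could not be parsed; message carries the offending location."""


class MissingControlError(IdrmapError):
    """A required non-deuterated or maximally-labelled control is absent."""


class DegeneratePeptideError(IdrmapError):
    """A peptide has no dynamic range (m_max == m_0, e.g. zero exchangeable amides)."""


class DegenerateFitError(IdrmapError):
    """A fit has no information content (e.g. flat anisotropy response)."""


class InsufficientDesignError(IdrmapError, ValueError):
    """An experimental design is too small to be analysed (e.g. <4 titration points)."""


class ConsistencyError(IdrmapError, ValueError):
    """Two inputs that must share numbering or residue types disagree."""


class ConfigError(IdrmapError, ValueError):
    """A configuration file contains unknown keys or malformed values."""
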