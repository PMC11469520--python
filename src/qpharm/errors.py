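"""Exception hierarchy shared across the package."""


class QPharmError(Exception):
    """Base class for all errors raised by qpharm."""


class FormatError(QPharmError, ValueError):
    """A file could not be parsed (PDB, pharmacophore JSON, library JSONL)."""


class EmptyStructureError(QPharmError, ValueError):
    """A structure file contained no atoms."""


class MinimumSizeError(QPharmError, ValueError):
    """A pharmacophore was smaller than the matcher's minimum of 3 features."""


class InvalidActionError(QPharmError, ValueError):
    """An MDP action was taken that the current proposal set does not allow."""


class ContractError(QPharmError, ValueError):
    """An input violated an interface contract (shapes, missing embeddings...)."""


class GenerationError(QPharmError, RuntimeError):
    """A synthetic-data generator could not satisfy its verification oracle."""


class ConfigError(QPharmError, ValueError):
    """A configuration file contained unknown keys or invalid values."""
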