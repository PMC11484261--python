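"""Exception hierarchy."""


class DualTCRError(Exception):
    """Base class for all package errors."""


class SchemaError(DualTCRError):
    """An input table is missing a required column or has an unparseable row."""


class ContractError(DualTCRError):
    """An operation was called on input violating its precondition."""


class EmptySampleError(DualTCRError):
    """A per-sample summary was requested for a sample with no paired cells."""


class ZeroVarianceError(DualTCRError):
    """A statistical test is undefined because the data carry no variance."""


class ConfigError(DualTCRError):
    """A simulation or pipeline configuration is internally inconsistent."""
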