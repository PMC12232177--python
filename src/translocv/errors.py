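"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid or inconsistent configuration values."""


class SchemaError(ValueError):
    """Mismatched table/model shapes, inventories or file headers."""


class InputError(ValueError):
    """Empty or otherwise unusable input data."""


class IntegrationError(RuntimeError):
    """Dynamics diverged; message names the offending frame."""


class TrainingDivergenceError(RuntimeError):
    """A training loss became non-finite; message names the epoch."""


class SamplingError(RuntimeError):
    """A biased-sampling update received a non-finite CV sample."""


class AtomResolutionError(KeyError):
    """A named atom/residue could not be resolved in a structure."""


class ContactDefinitionError(ValueError):
    """A contact definition is internally inconsistent."""


class ConnectivityError(RuntimeError):
    """Path endpoints are not connected through estimated cells."""


class UndefinedResultError(RuntimeError):
    """The requested statistic is undefined on this input."""
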