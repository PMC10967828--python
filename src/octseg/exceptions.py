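"""Exception hierarchy for octseg."""


class OctSegError(Exception):
    """Base class for all octseg errors."""


class ConfigurationError(OctSegError, ValueError):
    """A configuration object violates one of its invariants."""


class ArgumentError(OctSegError, ValueError):
    """An operation received an argument outside its contract."""


class DataError(OctSegError, ValueError):
    """Input data (images, masks, datasets) violates a precondition."""


class TrainingDivergedError(OctSegError, RuntimeError):
    """Training aborted because the loss became non-finite."""
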