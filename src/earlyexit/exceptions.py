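"""Exception hierarchy for early-exit inference errors."""


class EarlyExitError(Exception):
    """Base class for all package errors."""


class InvalidDistributionError(EarlyExitError):
    """A probability vector is empty, negative, or does not sum to one."""


class InvalidClassSpaceError(EarlyExitError):
    """The class space has fewer than two classes."""


class InvalidLayerError(EarlyExitError):
    """A layer index lies outside [1, M]."""


class InvalidTrajectoryError(EarlyExitError):
    """A per-layer probability trajectory is empty or malformed."""


class ConfigurationError(EarlyExitError):
    """A model, policy, or training configuration violates its invariants."""


class DataError(EarlyExitError):
    """A dataset is empty or carries labels outside the class space."""


class InputError(EarlyExitError):
    """A sample contains out-of-vocabulary tokens or exceeds the position limit."""
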