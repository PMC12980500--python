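class ConfigurationError(ValueError):
    """A configuration value violates a stated precondition."""


class CapabilityError(ValueError):
    """An operation was asked to handle a model/layer type it does not support."""


class SplitError(ValueError):
    """A requested data split is infeasible."""
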