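"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter, shape or file option is inconsistent with the model."""


class DegenerateInputError(ValueError):
    """An input carries too little observed data for the operation."""


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""
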