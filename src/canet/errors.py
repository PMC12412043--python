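"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A config value is invalid or incompatible with the chosen component."""


class ShapeError(ValueError):
    """A tensor violated a spatial/channel contract."""
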