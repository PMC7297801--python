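"""Exception hierarchy shared across the package."""


class GuvQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GuvQuantError):
    """Invalid configuration or input metadata (CLI exit code 2)."""


class SceneError(GuvQuantError):
    """A synthetic scene specification is ill-posed (e.g. overlapping rims)."""


class QuantificationError(GuvQuantError):
    """An image cannot be quantified (CLI exit code 3)."""
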