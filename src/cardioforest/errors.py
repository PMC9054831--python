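"""Exception hierarchy shared across the package."""


class CardioforestError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CardioforestError):
    """A file is missing or not in the expected on-disk format."""


class IntegrityError(CardioforestError):
    """File contents are internally inconsistent (dimensions, duplicates)."""


class ConfigError(CardioforestError):
    """A simulation or pipeline configuration is invalid."""


class EstimationError(CardioforestError):
    """A statistical quantity is unidentifiable from the given inputs."""
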