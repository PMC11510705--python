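"""Exception hierarchy for the pipeline."""


class BpfrayError(Exception):
    """Base class for all package errors."""


class FormatError(BpfrayError):
    """A file could not be parsed (bad header, bad field, bad record)."""


class ValidationError(BpfrayError):
    """Parsed data violates a documented invariant."""


class DegenerateGeometryError(BpfrayError):
    """A geometric operation received collinear/coincident points."""


class SelectionError(BpfrayError):
    """An atom selection did not resolve uniquely in a frame set."""


class ConfigError(BpfrayError):
    """A simulation or analysis configuration is inconsistent."""


class FitError(BpfrayError):
    """A regression or nonlinear fit could not be performed."""
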