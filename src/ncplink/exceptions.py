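"""Exception hierarchy for ncplink."""


class NcplinkError(Exception):
    """Base class for all ncplink errors."""


class InputFormatError(NcplinkError, ValueError):
    """A malformed edge-list file (wrong field count, empty fields, empty file)."""


class IncompatibilityError(NcplinkError, ValueError):
    """Two labelled objects that must agree (names, roles, shapes) do not."""


class DegenerateBandwidthError(NcplinkError, ZeroDivisionError):
    """All interaction profiles are zero: the kernel bandwidth is undefined."""


class ParameterError(NcplinkError, ValueError):
    """A parameter outside its valid range (weight, bandwidth, fold count, ...)."""


class EvaluationError(NcplinkError, ValueError):
    """A cross-validation request that cannot be satisfied (empty score lists, ...)."""


class MaskingError(NcplinkError, ValueError):
    """An attempt to mask an association that is not present."""
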