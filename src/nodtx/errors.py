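"""Exception hierarchy shared across the package."""


class NodtxError(Exception):
    """Base class for all package errors."""


class FormatError(NodtxError):
    """Malformed input file (bad header, bad column, bad character)."""


class CoordinateError(NodtxError):
    """Feature or alignment coordinates outside the reference."""


class ParameterError(NodtxError):
    """Invalid parameter combination."""


class StateError(NodtxError):
    """Operation applied to records in the wrong state."""


class InconsistentInputError(NodtxError):
    """Inputs that contradict each other (e.g. alignment longer than sequence)."""
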