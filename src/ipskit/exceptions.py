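"""Exception hierarchy.

``InputError`` marks malformed or out-of-domain inputs (CLI exit code 2 when
raised during argument handling, 3 during computation); ``DataError`` marks
invariant violations discovered inside otherwise well-formed data;
``EstimationError`` marks histograms from which no genome-size estimate can
be formed.
"""


class IpskitError(Exception):
    """Base class for all package errors."""


class InputError(IpskitError, ValueError):
    """Invalid parameter or malformed input."""


class DataError(IpskitError, ValueError):
    """Well-formed input violating a documented invariant."""


class EstimationError(IpskitError, RuntimeError):
    """A k-mer histogram without a usable coverage peak."""
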