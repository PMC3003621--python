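"""Exception hierarchy.

ValidationError covers malformed inputs and configuration; NumericalError
covers linear-algebra or optimization failures (non-PD covariances,
likelihood decreases, CDF failures).
"""


class JointEBError(Exception):
    """Base class for all package errors."""


class ValidationError(JointEBError):
    """Input data, shape, or configuration problem."""


class NumericalError(JointEBError):
    """Numerical failure: non-PD matrix, likelihood decrease, CDF failure."""
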