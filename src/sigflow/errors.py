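"""Exception hierarchy.

``NetworkError`` and ``PanelError`` signal malformed inputs; ``DivergenceError``
and ``SingularSystemError`` signal numerical failure of the propagation solve.
"""


class SigflowError(Exception):
    """Base class for all package errors."""


class NetworkError(SigflowError, ValueError):
    """Invalid network structure or network file."""


class PanelError(SigflowError, ValueError):
    """Invalid condition/DAC panel or panel file."""


class DivergenceError(SigflowError, ArithmeticError):
    """The propagation iteration produced non-finite values.

    Typically means alpha * spectral_radius(W) >= 1; check
    :func:`sigflow.propagation.spectral_margin`.
    """


class SingularSystemError(SigflowError, ArithmeticError):
    """I - alpha*W is singular or numerically near-singular."""
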