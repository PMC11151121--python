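"""Exception hierarchy."""

from __future__ import annotations

import numpy as np


class CoophazError(Exception):
    """Base class for all package errors."""


class DataError(CoophazError, ValueError):
    """Invalid or inconsistent input data."""


class ConvergenceError(CoophazError, RuntimeError):
    """Optimizer exhausted its iteration budget without meeting the
    gradient tolerance.

    Carries the last iterate and its gradient norm so callers can inspect
    (or deliberately accept) the partial result.
    """

    def __init__(self, message: str, last_iterate: np.ndarray | None = None,
                 grad_norm: float | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.grad_norm = grad_norm
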