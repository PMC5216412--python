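"""Single-step mutation model (SMM) transition probabilities.

Under the SMM each mutation shifts the repeat count by +1 or -1 with equal
probability.  With mutations arriving as a Poisson process, the probability
of a net change of ``k`` repeats after an expected ``theta = mu * t``
mutations is

    P(k | theta) = exp(-theta) * I_|k|(theta)

with ``I`` the modified Bessel function of the first kind (the Skellam
distribution of the difference of two Poisson(theta/2) counts).
"""

from __future__ import annotations

import numpy as np
from scipy.special import ive

__all__ = ["smm_transition_logprob", "smm_transition_prob", "smm_kernel"]


def smm_transition_logprob(k, theta):
    """Log-probability of a net repeat change ``k`` given ``theta = mu*t``.

    Evaluated as ``log(ive(|k|, theta))`` (the exponentially scaled Bessel
    function), which is stable for theta up to at least 1e4.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be >= 0")
    k = np.abs(np.asarray(k))
    with np.errstate(divide="ignore"):
        out = np.log(ive(k, theta))
    # theta == 0: point mass at k == 0
    out = np.where(theta == 0, np.where(k == 0, 0.0, -np.inf), out)
    return out if out.ndim else float(out)


def smm_transition_prob(k, theta):
    """Probability of a net repeat change ``k`` given ``theta = mu*t``."""
    return np.exp(smm_transition_logprob(k, theta))


def smm_kernel(theta: float, width: int) -> np.ndarray:
    """Vector ``[P(0|theta), P(1|theta), ..., P(width-1|theta)]``."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return smm_transition_prob(np.arange(width), theta)
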