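"""Link functions for cumulative boundary probabilities.

The graded response model puts a monotone link on the linear predictor
``a . theta + d_t``.  Two links are supported: the normal-ogive (probit)
link and the logistic link.  Slopes on the two metrics differ by the usual
~1.7 scaling constant, so a bank calibrated on one metric must not be
evaluated under the other without rescaling.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr

_SQRT_2PI = np.sqrt(2.0 * np.pi)

LINKS = ("probit", "logistic")


def link_cdf(z: np.ndarray, link: str) -> np.ndarray:
    """Cumulative probability of the link distribution at ``z``."""
    if link == "probit":
        return ndtr(z)
    if link == "logistic":
        return expit(z)
    raise ValueError(f"unknown link {link!r}; expected one of {LINKS}")


def link_pdf(z: np.ndarray, link: str) -> np.ndarray:
    """Density of the link distribution at ``z`` (derivative of the CDF)."""
    if link == "probit":
        return np.exp(-0.5 * np.square(z)) / _SQRT_2PI
    if link == "logistic":
        p = expit(z)
        return p * (1.0 - p)
    raise ValueError(f"unknown link {link!r}; expected one of {LINKS}")
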