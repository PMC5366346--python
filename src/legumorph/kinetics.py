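"""Logistic organ-expansion kinetics in phyllochronic time.

Every organ of a phytomer expands along the same three-parameter logistic,
``L(tau)/L_max = 1 / (1 + exp(-s * (tau - t50)))``, with time ``tau`` counted
in phyllochrons since the appearance of the bearer leaf.  The steepness ``s``
maps one-to-one onto the 5-95 % expansion duration ``d95 = 2*ln(19)/s``.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigurationError

#: 2*ln(0.95/0.05) -- the logistic span between its 5 % and 95 % points.
TWO_LN19 = 2.0 * math.log(19.0)


def logistic_fraction(tau, s: float, t50: float):
    """Relative organ size at phyllochronic time ``tau``.

    Parameters
    ----------
    tau : float or array
        Phyllochrons elapsed since the bearer leaf appeared.
    s : float
        Steepness (phyllochron^-1), must be positive.
    t50 : float
        Phyllochronic time of half expansion (leaflet convention: 0).
    """
    if s <= 0:
        raise ConfigurationError(f"logistic steepness must be positive, got {s}")
    z = np.clip(np.multiply(s, np.subtract(tau, t50)), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-z))


def d95_from_s(s: float) -> float:
    """5-95 % expansion duration (phyllochrons) from the steepness ``s``."""
    if s <= 0:
        raise ConfigurationError(f"steepness s must be positive, got {s}")
    return TWO_LN19 / s


def s_from_d95(d95: float) -> float:
    """Logistic steepness (phyllochron^-1) from a 5-95 % duration ``d95``."""
    if d95 <= 0:
        raise ConfigurationError(f"d95 must be positive, got {d95}")
    return TWO_LN19 / d95
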