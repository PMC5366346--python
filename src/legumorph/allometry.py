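"""Leaf-area allometry shared by all packaged species.

The area of a whole (compound) leaf is proportional to the product of the
central leaflet length, the central leaflet width and the number of leaflets,
with a single shape coefficient common to all species.
"""

from __future__ import annotations

import numpy as np

from .errors import DataValidationError

#: Shape coefficient of the common leaf-area allometry LA = c * L * l * n.
ALLOMETRY_COEFFICIENT = 0.694


def leaf_area(central_leaflet_length, central_leaflet_width, n_leaflets,
              coefficient: float = ALLOMETRY_COEFFICIENT):
    """Leaf area (cm^2) from central leaflet length/width (cm) and leaflet count.

    Accepts scalars or arrays; raises :class:`DataValidationError` on negative
    inputs.
    """
    length = np.asarray(central_leaflet_length, dtype=float)
    width = np.asarray(central_leaflet_width, dtype=float)
    n = np.asarray(n_leaflets, dtype=float)
    if np.any(length < 0) or np.any(width < 0) or np.any(n < 0):
        raise DataValidationError("leaf_area inputs must be non-negative")
    area = coefficient * length * width * n
    if area.ndim == 0:
        return float(area)
    return area
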