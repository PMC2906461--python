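"""Independent oracles used by the test suite.

The half-reaction oracle balances CxHyOzNw + a H2O -> x CO2 + w NH3 + b H+ +
b e- by solving the O and H conservation equations as a linear system; the
electron count b is obtained without ever summing valences, so it is an
independent check on the degree-of-reduction implementation.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


def half_reaction_electrons(elements: Mapping[str, float]) -> float:
    """Electrons released by complete oxidation to CO2/NH3, via balancing."""
    unsupported = set(elements) - {"C", "H", "O", "N"}
    if unsupported:
        raise ValueError(f"oracle only handles C/H/O/N, got {sorted(unsupported)}")
    x = elements.get("C", 0.0)
    y = elements.get("H", 0.0)
    z = elements.get("O", 0.0)
    w = elements.get("N", 0.0)
    # unknowns: a (water), b (protons = electrons)
    #   O: z + a = 2x        ->  a       = 2x - z
    #   H: y + 2a = 3w + b   ->  2a - b  = 3w - y
    coeffs = np.array([[1.0, 0.0], [2.0, -1.0]])
    rhs = np.array([2.0 * x - z, 3.0 * w - y])
    a, b = np.linalg.solve(coeffs, rhs)
    return float(b)


def balanced_oxidation_reaction(elements: Mapping[str, float]) -> dict[str, float]:
    """Full balanced oxidation with H2 as the electron carrier product.

    Returns name -> signed coefficient for {formula: -1, CO2, NH3, H2}; by
    construction the reaction conserves carbon and electron equivalents.
    """
    b = half_reaction_electrons(elements)
    return {
        "substrate": -1.0,
        "CO2": elements.get("C", 0.0),
        "NH3": elements.get("N", 0.0),
        "H2": b / 2.0,
    }
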