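"""Element lookup tables used by the hotspot grid.

Van der Waals radii are the Bondi values (Å); masses are standard atomic
weights (u).  Unknown elements raise rather than defaulting: a silently
wrong radius corrupts every downstream buriedness decision.
"""

from __future__ import annotations

import numpy as np

from .errors import UnknownElementError

# Bondi (1964) vdW radii, Å
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "SE": 1.90,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "ZN": 65.38,
    "SE": 78.971,
}


def vdw_radius(element: str) -> float:
    try:
        return VDW_RADII[element.strip().upper()]
    except KeyError:
        raise UnknownElementError(
            f"no van der Waals radius tabulated for element {element!r}"
        ) from None


def atomic_mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.strip().upper()]
    except KeyError:
        raise UnknownElementError(
            f"no atomic mass tabulated for element {element!r}"
        ) from None


def vdw_radii(elements) -> np.ndarray:
    return np.array([vdw_radius(e) for e in elements], dtype=float)


def atomic_masses(elements) -> np.ndarray:
    return np.array([atomic_mass(e) for e in elements], dtype=float)
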