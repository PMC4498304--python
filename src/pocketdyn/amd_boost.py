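"""Accelerated-MD boost-potential arithmetic.

Accelerated MD flattens energy wells by adding a boost dV whenever the
potential V lies below a threshold E_b:

    V* = V                      for V >= E_b
    V* = V + dV                 for V <  E_b
    dV = (E_b - V)^2 / (E_b - V + alpha)

with acceleration parameter alpha > 0.  The modified potential V* is
continuous at E_b, strictly increasing in V, and stays strictly below
E_b for all V < E_b.  This module evaluates the boost for single values
and energy series and derives (E_b, alpha) from simple per-system
heuristics; it does not run MD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoostParameters",
    "BoostEvaluation",
    "delta_v",
    "boost_series",
    "suggest_parameters",
    "PARAMETER_PRESETS",
]


@dataclass
class BoostParameters:
    """aMD threshold energy E_b and acceleration parameter alpha (kcal/mol)."""

    e_b: float
    alpha: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.e_b):
            raise ValueError("E_b must be finite")
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive")


@dataclass
class BoostEvaluation:
    """One evaluation: input V, boost dV >= 0, modified V* = V + dV."""

    v: float
    dv: float
    v_star: float


def delta_v(v: float, p: BoostParameters) -> BoostEvaluation:
    """Boost at potential ``v``: dV = (E_b - V)^2 / (E_b - V + alpha) below E_b."""
    v = float(v)
    if v >= p.e_b:
        return BoostEvaluation(v, 0.0, v)
    gap = p.e_b - v
    dv = gap * gap / (gap + p.alpha)
    return BoostEvaluation(v, dv, v + dv)


def boost_series(values, p: BoostParameters):
    """Elementwise boost over an energy series plus summary statistics.

    Returns ``(evaluations, summary)`` with summary keys ``mean_dv`` and
    ``fraction_boosted``; an empty series yields an empty, flagged
    summary.
    """
    evals = [delta_v(v, p) for v in values]
    if not evals:
        return [], {"empty": True, "mean_dv": float("nan"), "fraction_boosted": float("nan")}
    dvs = np.array([e.dv for e in evals])
    summary = {
        "empty": False,
        "mean_dv": float(dvs.mean()),
        "fraction_boosted": float((dvs > 0).mean()),
    }
    return evals, summary


# Placeholder presets: the coefficients with which (E_b, alpha) are derived
# from system size are system- and protocol-specific and must be overridden
# for production use.  "low" boosts gently, "high" raises the threshold
# further and shrinks alpha (stronger well-flattening).
PARAMETER_PRESETS = {
    "low": {"c_e": 0.16, "c_alpha": 0.16, "basis": "atoms"},
    "high": {"c_e": 0.32, "c_alpha": 0.08, "basis": "atoms"},
}


def suggest_parameters(
    average_potential: float,
    residue_count: int,
    atom_count: int,
    level: str = "low",
    coefficients: dict | None = None,
) -> BoostParameters:
    """Derive (E_b, alpha) as E_b = <V> + c_E * n, alpha = c_alpha * n.

    The count basis n (residues or atoms) and coefficients come from
    ``coefficients`` (keys ``c_e``, ``c_alpha``, ``basis``) or from the
    placeholder preset selected by ``level``; every choice is echoed in
    the metadata.
    """
    if residue_count <= 0 or atom_count <= 0:
        raise ValueError("counts must be positive")
    if coefficients is None:
        if level not in PARAMETER_PRESETS:
            raise KeyError(f"unknown level {level!r}; presets: {sorted(PARAMETER_PRESETS)}")
        coefficients = PARAMETER_PRESETS[level]
    for key in ("c_e", "c_alpha", "basis"):
        if key not in coefficients:
            raise KeyError(f"missing coefficient {key!r}")
    n = atom_count if coefficients["basis"] == "atoms" else residue_count
    e_b = float(average_potential) + coefficients["c_e"] * n
    alpha = coefficients["c_alpha"] * n
    return BoostParameters(
        e_b,
        alpha,
        metadata={
            "level": level,
            "coefficients": dict(coefficients),
            "count_basis": coefficients["basis"],
            "count": n,
            "residue_count": residue_count,
            "atom_count": atom_count,
            "average_potential": float(average_potential),
        },
    )
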