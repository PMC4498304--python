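"""Accelerated-MD boost potential over a synthetic energy series.

With threshold E_b = -480 kcal/mol and alpha = 20 kcal/mol, the boost
dV raises energies below E_b while keeping the modified potential V*
below the threshold and strictly increasing in V.
"""

import numpy as np

import pocketdyn as pk

p = pk.suggest_parameters(
    average_potential=-500.0, residue_count=10, atom_count=100,
    coefficients={"c_e": 0.2, "c_alpha": 0.2, "basis": "atoms"},
)
print(f"E_b = {p.e_b:.1f} kcal/mol, alpha = {p.alpha:.1f} kcal/mol")

for v in (p.e_b, p.e_b - p.alpha, p.e_b - 100.0):
    ev = pk.delta_v(v, p)
    print(f"V = {ev.v:8.1f}  dV = {ev.dv:7.3f}  V* = {ev.v_star:8.3f}")

rng = np.random.default_rng(0)
series = p.e_b + rng.normal(scale=40.0, size=1000)
_, summary = pk.boost_series(series, p)
print(f"series: mean dV = {summary['mean_dv']:.3f} kcal/mol, "
      f"fraction boosted = {summary['fraction_boosted']:.3f}")
# dV is 0 at the threshold, alpha/2 one alpha below it, and approaches
# (E_b - V) - alpha in deep wells, so V* saturates just under E_b.
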