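"""qRRHO Gibbs energies and Boltzmann populations.

Shows how the damped vibrational entropy keeps soft torsional modes finite,
and how relative Gibbs energies convert into conformer populations.
"""

import numpy as np

from enref import ThermoInput, boltzmann_average, boltzmann_populations, qrrho_gibbs
from enref.thermo import _s_free_rotor, _s_harmonic, damping_weight

# a soft 15 cm⁻¹ torsion: harmonic vs damped entropy (cal/mol/K)
nu = 15.0
s_ho = float(_s_harmonic(np.array([nu]), 298.15)[0]) * 1000
s_fr = float(_s_free_rotor(np.array([nu]), 298.15)[0]) * 1000
w = damping_weight(nu)
print(f"mode at {nu} cm⁻¹: S_harmonic = {s_ho:.2f}, S_free_rotor = {s_fr:.2f}, "
      f"damped = {w * s_ho + (1 - w) * s_fr:.2f} cal/(mol·K)  (w = {w:.4f})")

# Gibbs energy of a toy molecule with a mixed spectrum
inp = ThermoInput(
    frequencies=np.array([35.0, 120.0, 450.0, 1100.0, 1650.0, 2900.0]),
    moments_of_inertia=np.array([15.0, 40.0, 52.0]),  # u·Å²
    molecular_mass=60.0,
)
res = qrrho_gibbs(0.0, inp)
print(f"ZPE = {res.zpe:.3f} kcal/mol, H_corr = {res.h_corr:.3f} kcal/mol, "
      f"S = {res.s_total:.2f} cal/(mol·K), G − E_el = {res.gibbs:.3f} kcal/mol")

# populations over three conformers 0 / 0.5 / 1.0 kcal/mol apart
energies = [0.0, 0.5, 1.0]
pops = boltzmann_populations(energies, temperature=298.15)
for e, p in zip(energies, pops):
    print(f"  ΔG = {e:.2f} kcal/mol → population {100 * p:.1f}%")
print(f"ensemble-averaged energy: {boltzmann_average(energies, pops):.4f} kcal/mol")
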