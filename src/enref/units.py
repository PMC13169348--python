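"""Physical constants and unit conversions.

Internal conventions: energies in kcal/mol, coordinates in Å, rotational
constants in MHz, frequencies in cm⁻¹, temperature in K.
"""

from scipy import constants as _c

#: CODATA Hartree → kcal/mol
HARTREE_TO_KCAL = 627.5094740631

#: Gas constant in kcal/(mol·K)
R_KCAL = 1.987204e-3

#: Gas constant in cal/(mol·K)
R_CAL = R_KCAL * 1000.0

#: Joule per mole → kcal/mol
J_MOL_TO_KCAL = 1.0 / (_c.calorie * 1000.0)

#: Planck constant, J·s
PLANCK = _c.h

#: Boltzmann constant, J/K
KBOLTZ = _c.k

#: Avogadro constant, 1/mol
AVOGADRO = _c.N_A

#: Speed of light, cm/s
C_CM = _c.c * 100.0

#: Atomic mass unit, kg
AMU = _c.atomic_mass

#: u·Å² → kg·m²
UA2_TO_KGM2 = AMU * 1e-20

#: cm⁻¹ ↔ MHz
CM1_TO_MHZ = _c.c / 1e4  # ν[MHz] = ν̃[cm⁻¹]·c[m/s]·100/1e6 = ν̃·29979.2458


def hartree_to_kcal(e_hartree: float) -> float:
    """Convert an electronic energy from Hartree to kcal/mol."""
    return e_hartree * HARTREE_TO_KCAL


def ev_fwhm_to_nm(fwhm_ev: float, wavelength_nm: float) -> float:
    """Convert an energy-domain FWHM (eV) to a wavelength FWHM (nm) at a band center.

    Uses dλ = λ²/(hc)·dE with hc = 1239.84198 eV·nm; useful because electronic
    broadenings are usually quoted in eV while UV/ECD spectra are plotted in nm.
    """
    hc_ev_nm = _c.h * _c.c / _c.e * 1e9
    return wavelength_nm**2 * fwhm_ev / hc_ev_nm
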