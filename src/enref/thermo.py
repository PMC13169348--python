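"""Quasi-RRHO thermochemistry and Boltzmann ensemble statistics.

Gibbs free energies are built from the standard ideal-gas partition functions
(translation, rigid rotor, harmonic oscillator). Low-frequency vibrational
entropies are interpolated toward the free-rotor limit with the damping
function w(ν) = 1/(1 + (ν₀/ν)^α), so that soft torsional modes do not make the
entropy diverge as they do in the pure harmonic oscillator. Enthalpy and ZPE
remain harmonic; only the entropy is damped.

Populations follow p_i ∝ g_i·exp(−ΔE_i/RT), with ΔE_i relative to the
ensemble minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import DataError
from .units import AMU, AVOGADRO, C_CM, J_MOL_TO_KCAL, KBOLTZ, PLANCK, R_KCAL, UA2_TO_KGM2

__all__ = [
    "ThermoInput",
    "ThermoResult",
    "damping_weight",
    "qrrho_gibbs",
    "boltzmann_populations",
    "boltzmann_average",
]

#: free-rotor averaging moment of the damping scheme, kg·m²
B_AV = 1e-44

_ATM_PA = 101325.0


@dataclass
class ThermoInput:
    """Inputs to a qRRHO evaluation for one conformer.

    frequencies : harmonic wavenumbers, cm⁻¹ (imaginary modes must be removed
        upstream; see :func:`drop_imaginary`)
    moments_of_inertia : principal moments, u·Å² — 3 values, 2 for a linear
        molecule, empty for a single atom
    molecular_mass : u
    symmetry_number : external rotational symmetry number σ
    temperature : K
    pressure : atm
    nu0 : damping reference wavenumber, cm⁻¹
    alpha : damping exponent
    """

    frequencies: np.ndarray
    moments_of_inertia: np.ndarray
    molecular_mass: float
    symmetry_number: int = 1
    temperature: float = 298.15
    pressure: float = 1.0
    nu0: float = 100.0
    alpha: float = 4.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.moments_of_inertia = np.asarray(self.moments_of_inertia, dtype=float)
        if self.temperature <= 0:
            raise DataError("temperature must be positive")
        if np.any(self.frequencies < 0):
            raise DataError("frequencies must be non-negative (drop imaginary modes first)")
        if self.nu0 <= 0:
            raise DataError("nu0 must be positive")


@dataclass
class ThermoResult:
    """Thermal corrections, kcal/mol (entropy in cal/(mol·K))."""

    zpe: float
    h_corr: float
    s_total: float
    gibbs: float
    components: dict = field(default_factory=dict)


def damping_weight(nu: float | np.ndarray, nu0: float = 100.0, alpha: float = 4.0):
    """Head-Gordon style switching weight w(ν) = 1/(1 + (ν₀/ν)^α).

    Approaches 1 for stiff modes (harmonic limit) and 0 as ν → 0 (free-rotor
    limit); w(ν₀) = 1/2.
    """
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise DataError("damping weight requires strictly positive wavenumbers")
    out = 1.0 / (1.0 + (nu0 / nu) ** alpha)
    return float(out) if out.ndim == 0 else out


def drop_imaginary(frequencies: np.ndarray) -> np.ndarray:
    """Remove imaginary (negative) modes, warning how many were dropped.

    Transition-state workflows legitimately produce exactly one; it must not
    enter the vibrational entropy.
    """
    freqs = np.asarray(frequencies, dtype=float)
    n_imag = int(np.sum(freqs < 0))
    if n_imag:
        warnings.warn(
            f"dropping {n_imag} imaginary frequenc{'y' if n_imag == 1 else 'ies'} "
            "before thermochemistry",
            stacklevel=2,
        )
    return freqs[freqs >= 0]


def _s_harmonic(freqs: np.ndarray, T: float) -> np.ndarray:
    """Per-mode harmonic-oscillator entropy, kcal/(mol·K)."""
    x = PLANCK * C_CM * freqs / (KBOLTZ * T)
    return R_KCAL * (x / np.expm1(x) - np.log(-np.expm1(-x)))

def _s_free_rotor(freqs: np.ndarray, T: float) -> np.ndarray:
    """Per-mode free-rotor entropy with the averaged-moment damping, kcal/(mol·K)."""
    mu = PLANCK / (8.0 * np.pi**2 * C_CM * freqs)
    mu_eff = mu * B_AV / (mu + B_AV)
    arg = np.sqrt(8.0 * np.pi**3 * mu_eff * KBOLTZ * T) / PLANCK
    return R_KCAL * (0.5 + np.log(arg))


def qrrho_gibbs(e_el: float, inp: ThermoInput) -> ThermoResult:
    """Gibbs free energy G = E_el + ZPE + H_corr(T) − T·S_total under qRRHO.

    Vibrational entropy per mode is w·S_HO + (1−w)·S_FR; ZPE and thermal
    enthalpy stay harmonic. Works for atoms (no modes, no rotation), linear
    molecules (2 moments) and general tops (3 moments).
    """
    T = inp.temperature
    freqs = inp.frequencies[inp.frequencies > 0]
    moments = inp.moments_of_inertia[inp.moments_of_inertia > 0]
    rt = R_KCAL * T

    # translation (ideal gas at the given pressure)
    m_kg = inp.molecular_mass * AMU
    v = KBOLTZ * T / (inp.pressure * _ATM_PA)
    q_trans = (2.0 * np.pi * m_kg * KBOLTZ * T / PLANCK**2) ** 1.5 * v
    s_trans = R_KCAL * (np.log(q_trans) + 2.5)
    h_trans = 2.5 * rt  # 3/2 RT kinetic + PV

    # rotation
    if moments.size == 0:
        s_rot, h_rot = 0.0, 0.0
    else:
        theta = PLANCK**2 / (8.0 * np.pi**2 * moments * UA2_TO_KGM2 * KBOLTZ)
        if moments.size <= 2:  # linear top: two equal finite moments (or one given)
            q_rot = T / (inp.symmetry_number * float(np.mean(theta)))
            s_rot = R_KCAL * (np.log(q_rot) + 1.0)
            h_rot = rt
        else:
            q_rot = np.sqrt(np.pi * T**3 / np.prod(theta)) / inp.symmetry_number
            s_rot = R_KCAL * (np.log(q_rot) + 1.5)
            h_rot = 1.5 * rt

    # vibration
    if freqs.size:
        x = PLANCK * C_CM * freqs / (KBOLTZ * T)
        zpe = float(np.sum(0.5 * PLANCK * C_CM * freqs) * AVOGADRO * J_MOL_TO_KCAL)
        h_vib = float(np.sum(rt * x / np.expm1(x)))
        w = damping_weight(freqs, inp.nu0, inp.alpha)
        s_vib = float(np.sum(w * _s_harmonic(freqs, T) + (1.0 - w) * _s_free_rotor(freqs, T)))
    else:
        zpe, h_vib, s_vib = 0.0, 0.0, 0.0

    h_corr = h_trans + h_rot + h_vib
    s_total = s_trans + s_rot + s_vib
    gibbs = e_el + zpe + h_corr - T * s_total
    return ThermoResult(
        zpe=zpe,
        h_corr=h_corr,
        s_total=s_total * 1000.0,  # cal/(mol·K)
        gibbs=gibbs,
        components={
            "S_trans": s_trans * 1000.0,
            "S_rot": s_rot * 1000.0,
            "S_vib": s_vib * 1000.0,
            "H_trans": h_trans,
            "H_rot": h_rot,
            "H_vib": h_vib,
        },
    )


def boltzmann_populations(
    energies, degeneracies=None, temperature: float = 298.15
) -> np.ndarray:
    """Degenerate Boltzmann populations p_i ∝ g_i·exp(−ΔE_i/RT).

    Energies in kcal/mol; ΔE_i is taken relative to the minimum, which leaves
    the populations invariant under any constant energy shift. The result sums
    to 1 to machine precision.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise DataError("cannot compute populations of an empty ensemble")
    if temperature <= 0:
        raise DataError("temperature must be positive")
    g = (
        np.ones_like(e)
        if degeneracies is None
        else np.asarray(degeneracies, dtype=float)
    )
    if g.shape != e.shape:
        raise DataError("energies and degeneracies must have the same length")
    log_w = np.log(g) - (e - e.min()) / (R_KCAL * temperature)
    p = np.exp(log_w - logsumexp(log_w))
    return p / p.sum()


def boltzmann_average(energies, populations) -> float:
    """Population-weighted ensemble average E_av = Σ p_i·E_i (kcal/mol)."""
    e = np.asarray(energies, dtype=float)
    p = np.asarray(populations, dtype=float)
    if e.shape != p.shape:
        raise DataError("energies and populations must have the same length")
    if abs(p.sum() - 1.0) > 1e-9:
        raise DataError(f"populations sum to {p.sum():.12f}, expected 1")
    return float(np.dot(p, e))
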