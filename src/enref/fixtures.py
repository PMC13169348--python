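"""Deterministic synthetic test data with known ground truth.

Two generators: chain-like conformer ensembles with planted duplicates (so
every pruning decision can be scored exactly) and stick/«experimental»
spectrum pairs built at known broadening and shift (so alignment recovery can
be validated). Both are pure functions of their seed.

The chain geometries are not real molecules: torsional perturbations of a
zig-zag backbone produce the kind of rotational-constant and
distance-eigenvalue variation real conformers show, without any force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Conformer, Ensemble, rotational_constants
from .errors import ConfigError
from .spectra import (
    CHIRAL_KINDS,
    ContinuousSpectrum,
    ConvolutionParams,
    ImpulseSpectrum,
    convolute,
)

__all__ = ["FixtureSpec", "make_ensemble", "make_spectrum_pair"]

_CHAIN_ELEMENTS = ["C", "N", "O"]


@dataclass
class FixtureSpec:
    """Recipe for a synthetic ensemble.

    n_planted_duplicates conformers are exact geometric copies of earlier
    ones whose energies differ by less than ``duplicate_jitter`` — below any
    sensible thrG — so dual-filter pruning must remove exactly that many.
    """

    n_conformers: int = 20
    n_atoms: int = 8
    n_planted_duplicates: int = 0
    energy_spread: float = 5.0
    duplicate_jitter: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_duplicates >= self.n_conformers:
            raise ConfigError("need fewer planted duplicates than conformers")
        if self.energy_spread <= 0:
            raise ConfigError("energy_spread must be positive")


def _chain_geometry(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """Zig-zag chain with seeded torsional/bond perturbations."""
    coords = np.zeros((n_atoms, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_atoms):
        bond = 1.45 + 0.1 * rng.standard_normal()
        theta = np.deg2rad(109.5 + 8.0 * rng.standard_normal())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        step = np.array(
            [
                np.cos(theta),
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
            ]
        )
        # rotate the step roughly along the previous direction
        step = 0.6 * direction + step
        step /= np.linalg.norm(step)
        coords[i] = coords[i - 1] + bond * step
        direction = step
    return coords


def make_ensemble(spec: FixtureSpec) -> tuple[Ensemble, dict]:
    """Build a synthetic ensemble plus a ground-truth record.

    The record lists which conformer indices are planted duplicates (and of
    which original), plus the true ascending-energy order of the originals.
    """
    rng = np.random.default_rng(spec.seed)
    n_orig = spec.n_conformers - spec.n_planted_duplicates
    symbols = [
        _CHAIN_ELEMENTS[i % len(_CHAIN_ELEMENTS)] for i in range(spec.n_atoms)
    ]
    conformers: list[Conformer] = []
    energies = np.sort(rng.uniform(0.0, spec.energy_spread, n_orig))
    rng.shuffle(energies)
    for i in range(n_orig):
        coords = _chain_geometry(spec.n_atoms, rng)
        conf = Conformer(symbols=symbols, coords=coords, e_el=float(energies[i]), index=i)
        _, conf.b_norm = rotational_constants(conf)
        conformers.append(conf)

    duplicates: dict[int, int] = {}
    for j in range(spec.n_planted_duplicates):
        src = int(rng.integers(0, n_orig))
        idx = n_orig + j
        copy = conformers[src].copy()
        copy.index = idx
        # sub-threshold jitter, strictly positive so the original stays lower
        copy.e_el = conformers[src].e_el + float(
            rng.uniform(1e-4, spec.duplicate_jitter)
        )
        conformers.append(copy)
        duplicates[idx] = src

    ens = Ensemble(conformers=conformers)
    truth = {
        "duplicates": duplicates,
        "energy_order": [c.index for c in sorted(conformers, key=lambda c: c.e_el)],
        "n_originals": n_orig,
    }
    return ens, truth


def make_spectrum_pair(
    gamma_true: float,
    shift_true: float,
    kind: str = "IR",
    seed: int = 0,
    n_sticks: int = 12,
    noise: float = 0.0,
) -> tuple[ImpulseSpectrum, ContinuousSpectrum, dict]:
    """Random sticks plus the «experimental» curve convoluted at known (γ, Δ).

    Vibrational kinds get sticks in 900–1700 cm⁻¹ on a grid padded well past
    the band edges; electronic kinds sticks in 220–380 nm. Chiral kinds carry
    signed intensities. Optional Gaussian noise (fraction of the curve
    maximum) perturbs the experimental trace deterministically.
    """
    rng = np.random.default_rng(seed)
    vibrational = kind in ("IR", "VCD")
    lo, hi = (900.0, 1700.0) if vibrational else (220.0, 380.0)
    positions = np.sort(rng.uniform(lo, hi, n_sticks))
    intensities = rng.uniform(0.2, 1.0, n_sticks)
    if kind in CHIRAL_KINDS:
        intensities *= rng.choice([-1.0, 1.0], n_sticks)
    imp = ImpulseSpectrum(kind, positions, intensities)
    pad = 100.0 if vibrational else 60.0
    grid = np.linspace(lo - pad, hi + pad, 1200)
    exp = convolute(imp, ConvolutionParams(gamma=gamma_true, shift=shift_true), grid)
    if noise > 0:
        scale = noise * np.max(np.abs(exp.values))
        exp = ContinuousSpectrum(grid, exp.values + scale * rng.standard_normal(grid.size))
    truth = {"gamma": gamma_true, "shift": shift_true, "kind": kind, "seed": seed}
    return imp, exp, truth
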