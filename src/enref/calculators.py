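"""Calculator contract and the built-in synthetic calculator.

The refinement engine talks to quantum-chemistry backends through a tiny
contract: a set of declared capabilities and one ``evaluate`` call returning
the electronic energy and, when requested, relaxed coordinates, harmonic
frequencies, and spectral impulses. Adapters for real engines implement this
surface; the synthetic calculator implements it with a cheap, fully
deterministic model so the whole pipeline runs and tests without any QM code.

Synthetic model: the energy is a sum of smooth Morse-like pair terms over
interatomic distances (translation/rotation invariant by construction) plus a
fixed per-multiplicity offset; optimisation is bounded quasi-Newton descent
on that surface; frequencies are eigenvalues of a pairwise-spring Hessian
built with the current geometry as its rest configuration (hence positive
semidefinite); impulses reuse the frequencies with seeded intensities.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from .ensemble import Conformer, atomic_mass
from .errors import ConfigError
from .spectra import ImpulseSpectrum
from .units import AMU, AVOGADRO, C_CM, J_MOL_TO_KCAL

__all__ = ["CalcResult", "Calculator", "SyntheticCalculator", "MULT_OFFSET_KCAL"]

#: energy raised per unit of spin multiplicity above singlet, kcal/mol
MULT_OFFSET_KCAL = 10.0

CAP_ENERGY = "energy"
CAP_OPTIMIZE = "optimize"
CAP_FREQUENCIES = "frequencies"
CAP_SPECTRA = "spectra_impulses"


@dataclass
class CalcResult:
    """Outcome of one calculator evaluation (energies in kcal/mol)."""

    e_el: float
    coords: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    impulses: dict[str, ImpulseSpectrum] = field(default_factory=dict)


class Calculator:
    """Abstract backend contract.

    Subclasses declare ``capabilities`` (a subset of {energy, optimize,
    frequencies, spectra_impulses}) and implement :meth:`evaluate`. Returned
    coordinate arrays must match the input atom count; frequencies are
    returned only when the step requests them.
    """

    capabilities: frozenset[str] = frozenset()

    def evaluate(self, step, conformer: Conformer) -> CalcResult:
        raise NotImplementedError

    def check_capabilities(self, required: set[str]) -> None:
        missing = set(required) - set(self.capabilities)
        if missing:
            raise ConfigError(
                f"calculator lacks required capabilities: {sorted(missing)}"
            )


def _pair_seed(seed: int, sym_a: str, sym_b: str, tag: str) -> int:
    key = f"{seed}:{tag}:{min(sym_a, sym_b)}-{max(sym_a, sym_b)}"
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big")


class SyntheticCalculator(Calculator):
    """Deterministic stand-in backend driven entirely by a seed.

    Parameters
    ----------
    seed : controls every pair parameter and intensity draw; identical seeds
        give bit-identical results on identical inputs.
    noise : optional magnitude (kcal/mol) of a geometry-dependent but
        deterministic energy perturbation, for stress-testing filters.
    """

    capabilities = frozenset({CAP_ENERGY, CAP_OPTIMIZE, CAP_FREQUENCIES, CAP_SPECTRA})

    def __init__(self, seed: int = 0, noise: float = 0.0, max_opt_steps: int = 60):
        self.seed = int(seed)
        self.noise = float(noise)
        self.max_opt_steps = int(max_opt_steps)
        self._pair_cache: dict[tuple[str, str], tuple[float, float, float]] = {}

    # -- synthetic potential -------------------------------------------------

    def _pair_params(self, sym_a: str, sym_b: str) -> tuple[float, float, float]:
        """(well depth kcal/mol, steepness 1/Å, rest length Å) per element pair."""
        key = (min(sym_a, sym_b), max(sym_a, sym_b))
        if key not in self._pair_cache:
            rng = np.random.default_rng(_pair_seed(self.seed, *key, "pair"))
            depth = 2.0 + 6.0 * rng.random()
            steep = 0.8 + 0.8 * rng.random()
            r0 = 1.2 + 1.6 * rng.random()
            self._pair_cache[key] = (depth, steep, r0)
        return self._pair_cache[key]

    def _energy(self, symbols: list[str], coords: np.ndarray, multiplicity: int) -> float:
        d = squareform(pdist(coords))
        n = len(symbols)
        e = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                depth, steep, r0 = self._pair_params(symbols[i], symbols[j])
                # Morse-like: bounded well, smooth everywhere
                e += depth * ((1.0 - np.exp(-steep * (d[i, j] - r0))) ** 2 - 1.0)
        e += (multiplicity - 1) * MULT_OFFSET_KCAL
        if self.noise:
            # deterministic "noise": a smooth function of the geometry
            e += self.noise * np.sin(1000.0 * d.sum())
        return float(e)

    def _optimize(self, symbols: list[str], coords: np.ndarray, multiplicity: int) -> np.ndarray:
        x0 = coords.ravel()

        def fun(x: np.ndarray) -> float:
            return self._energy(symbols, x.reshape(-1, 3), multiplicity)

        res = minimize(
            fun, x0, method="L-BFGS-B", options={"maxiter": self.max_opt_steps}
        )
        out = res.x if res.fun <= fun(x0) else x0
        return out.reshape(-1, 3)

    def _frequencies(self, symbols: list[str], coords: np.ndarray) -> np.ndarray:
        """Spring-network Hessian eigenvalues mapped to wavenumbers.

        Each atom pair gets a spring at its current distance, so the Hessian
        is positive semidefinite; the six (five for linear) rigid-body zeros
        are discarded.
        """
        n = len(symbols)
        d = squareform(pdist(coords))
        hess = np.zeros((3 * n, 3 * n))
        for i in range(n):
            for j in range(i + 1, n):
                depth, steep, _ = self._pair_params(symbols[i], symbols[j])
                k_spring = 2.0 * depth * steep**2 / max(d[i, j], 0.5)
                u = (coords[i] - coords[j]) / d[i, j]
                block = k_spring * np.outer(u, u)
                hess[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += block
                hess[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] += block
                hess[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= block
                hess[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] -= block
        masses = np.repeat([atomic_mass(s) for s in symbols], 3)
        mw = hess / np.sqrt(np.outer(masses, masses))
        eigvals = np.linalg.eigvalsh(mw)
        eigvals = eigvals[eigvals > 1e-8]
        # kcal/(mol·Å²·u) eigenvalues → angular frequency → cm⁻¹
        conv = 1.0 / (J_MOL_TO_KCAL * AVOGADRO) / (AMU * 1e-20)  # to 1/s²
        omega = np.sqrt(eigvals * conv)
        return omega / (2.0 * np.pi * C_CM)

    def _impulses(self, freqs: np.ndarray, conformer_index: int) -> dict[str, ImpulseSpectrum]:
        rng = np.random.default_rng((self.seed * 1000003 + conformer_index) % 2**31)
        n = freqs.size
        ir = ImpulseSpectrum("IR", freqs, rng.random(n), conformer_index)
        vcd = ImpulseSpectrum("VCD", freqs, rng.random(n) * 2.0 - 1.0, conformer_index)
        return {"IR": ir, "VCD": vcd}

    # -- contract ------------------------------------------------------------

    def evaluate(self, step, conformer: Conformer) -> CalcResult:
        kind = getattr(step, "kind", "single_point")
        multiplicity = getattr(step, "multiplicity", 1)
        coords = conformer.coords
        new_coords = None
        if kind in ("opt", "opt_freq"):
            new_coords = self._optimize(conformer.symbols, coords, multiplicity)
            coords = new_coords
        e_el = self._energy(conformer.symbols, coords, multiplicity)
        freqs = None
        impulses: dict[str, ImpulseSpectrum] = {}
        if kind in ("freq", "opt_freq"):
            freqs = self._frequencies(conformer.symbols, coords)
            impulses = self._impulses(freqs, conformer.index)
        return CalcResult(e_el=e_el, coords=new_coords, frequencies=freqs, impulses=impulses)
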