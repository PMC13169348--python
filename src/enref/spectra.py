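"""Ensemble spectra: convolution, weighting, similarity, and alignment.

Stick spectra from individual conformers are broadened with a Lorentzian
(IR/VCD, wavenumber domain) or a Gaussian (UV/ECD, wavelength domain), summed
with Boltzmann weights, and compared with experimental two-column XY traces.

The Lorentzian carries a multiplicative shift Δ on the stick positions (a
frequency-scaling factor); the Gaussian an additive shift (a band shift in
nm, where negative values move bands to shorter wavelength — a blue shift).
The Gaussian broadening parameter is σ = γ/(2√(2 ln 2)) with γ the FWHM.

The agreement metric is a weighted RMSD between max-normalised curves,
converted to a similarity index S = 1 − RMSD/max, where the largest possible
RMSD is 1 for achiral spectra and 2 for signed chiral ones. ``autoconvolute``
fits (γ, Δ) by bounded L-BFGS-B minimisation of that RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .errors import SpectrumError

__all__ = [
    "CHIRAL_KINDS",
    "ImpulseSpectrum",
    "ContinuousSpectrum",
    "ConvolutionParams",
    "WeightWindow",
    "FitResult",
    "convolute",
    "ensemble_spectrum",
    "weight_function",
    "weighted_rmsd",
    "similarity",
    "autoconvolute",
    "read_xy",
    "write_xy",
]

#: spectrum kinds with signed intensities
CHIRAL_KINDS = frozenset({"VCD", "ECD"})
#: kinds broadened with a Lorentzian in the wavenumber domain
VIBRATIONAL_KINDS = frozenset({"IR", "VCD"})
ALL_KINDS = frozenset({"IR", "VCD", "UV", "ECD"})

#: points of the uniform comparison grid spanning the experimental window
GRID_POINTS = 1000

#: floor of the taper region of the weighting window
WEIGHT_FLOOR = 0.15

#: default fit bounds: FWHM (grid units) and shift per domain
DEFAULT_GAMMA_BOUNDS = {"vibrational": (2.0, 24.0), "electronic": (5.0, 60.0)}
DEFAULT_SHIFT_BOUNDS = {"vibrational": (0.94, 1.02), "electronic": (-50.0, 50.0)}
#: default FWHM before any fitting, cm⁻¹ (vibrational) / nm (electronic)
DEFAULT_FWHM = {"vibrational": 8.0, "electronic": 20.0}

_SIGMA_OF_GAMMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _domain(kind: str) -> str:
    if kind not in ALL_KINDS:
        raise SpectrumError(f"unknown spectrum kind {kind!r}")
    return "vibrational" if kind in VIBRATIONAL_KINDS else "electronic"


@dataclass
class ImpulseSpectrum:
    """Stick spectrum of one conformer: positions (cm⁻¹ or nm) and intensities.

    Chiral kinds (VCD, ECD) may carry signed intensities; achiral ones must
    not.
    """

    kind: str
    positions: np.ndarray
    intensities: np.ndarray
    conformer_index: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        _domain(self.kind)
        if self.positions.shape != self.intensities.shape:
            raise SpectrumError("positions and intensities must have equal length")
        if np.any(self.positions <= 0):
            raise SpectrumError("impulse positions must be strictly positive")
        if self.kind not in CHIRAL_KINDS and np.any(self.intensities < 0):
            raise SpectrumError(f"{self.kind} intensities must be non-negative")


@dataclass
class ContinuousSpectrum:
    """Curve on a uniform ascending grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise SpectrumError("grid and values must have equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise SpectrumError("grid must be strictly increasing")

    def normalized(self) -> "ContinuousSpectrum":
        """Max-normalised copy (max|y| = 1)."""
        m = np.max(np.abs(self.values))
        if m == 0:
            raise SpectrumError("cannot normalise an identically zero spectrum")
        return ContinuousSpectrum(self.grid, self.values / m)

    def resampled(self, grid: np.ndarray) -> "ContinuousSpectrum":
        """Linear interpolation onto a new grid (zero outside the data range)."""
        y = np.interp(grid, self.grid, self.values, left=0.0, right=0.0)
        return ContinuousSpectrum(grid, y)


@dataclass
class ConvolutionParams:
    """FWHM γ (> 0, grid units) and shift Δ (multiplicative for IR/VCD,
    additive for UV/ECD; a multiplicative shift must be positive)."""

    gamma: float
    shift: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise SpectrumError("gamma (FWHM) must be positive")

    @property
    def sigma(self) -> float:
        return self.gamma * _SIGMA_OF_GAMMA


@dataclass
class WeightWindow:
    """Weighting window focusing the optimizer on a region of interest.

    Value 1 inside [x_int_min, x_int_max], 0 outside [x_exp_min, x_exp_max];
    in the taper regions a Gaussian centred at the nearer interior bound
    (σ = 0.1·|exterior − interior| on each side), floored at 0.15. When
    disabled, a plain step over the experimental window.
    """

    x_exp_min: float
    x_exp_max: float
    x_int_min: float | None = None
    x_int_max: float | None = None
    enabled: bool = True
    floor: float = WEIGHT_FLOOR

    def __post_init__(self) -> None:
        if self.x_int_min is None:
            self.x_int_min = self.x_exp_min
        if self.x_int_max is None:
            self.x_int_max = self.x_exp_max
        if not (self.x_exp_min <= self.x_int_min <= self.x_int_max <= self.x_exp_max):
            raise SpectrumError(
                "window bounds must satisfy x_exp_min ≤ x_int_min ≤ x_int_max ≤ x_exp_max"
            )

    @property
    def sigma1(self) -> float:
        return 0.1 * abs(self.x_exp_min - self.x_int_min)

    @property
    def sigma2(self) -> float:
        return 0.1 * abs(self.x_exp_max - self.x_int_max)


@dataclass
class FitResult:
    """Optimised broadening/shift with the final agreement metrics."""

    gamma: float
    shift: float
    rmsd: float
    similarity: float
    converged: bool
    gamma_bounds: tuple[float, float] = (0.0, 0.0)
    shift_bounds: tuple[float, float] = (0.0, 0.0)
    n_evaluations: int = 0
    extras: dict = field(default_factory=dict)


def convolute(
    imp: ImpulseSpectrum, params: ConvolutionParams, grid: np.ndarray
) -> ContinuousSpectrum:
    """Broaden a stick spectrum onto a grid.

    IR/VCD: L(X) = Σ_i I_i·γ²/(γ² + 4(X − ω_i·Δ)²) — each stick peaks at I_i.
    UV/ECD: G(X) = Σ_i I_i·(σ√(2π))⁻¹·exp(−(X − (ω_i + Δ))²/(2σ²)).
    """
    grid = np.asarray(grid, dtype=float)
    x = grid[:, None]
    if _domain(imp.kind) == "vibrational":
        centers = imp.positions * params.shift
        g2 = params.gamma**2
        y = np.sum(imp.intensities * g2 / (g2 + 4.0 * (x - centers) ** 2), axis=1)
    else:
        centers = imp.positions + params.shift
        s = params.sigma
        y = np.sum(
            imp.intensities
            / (s * np.sqrt(2.0 * np.pi))
            * np.exp(-0.5 * ((x - centers) / s) ** 2),
            axis=1,
        )
    return ContinuousSpectrum(grid, y)


def ensemble_spectrum(
    impulses: list[ImpulseSpectrum],
    populations,
    params: ConvolutionParams,
    grid: np.ndarray,
) -> ContinuousSpectrum:
    """Population-weighted sum of per-conformer convoluted spectra."""
    p = np.asarray(populations, dtype=float)
    if len(impulses) != p.size:
        raise SpectrumError(
            f"{len(impulses)} impulse sets but {p.size} populations"
        )
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for imp, pi in zip(impulses, p):
        total += pi * convolute(imp, params, grid).values
    return ContinuousSpectrum(grid, total)


def weight_function(x, win: WeightWindow):
    """Evaluate the weighting window at scalar or array x."""
    x = np.asarray(x, dtype=float)
    w = np.zeros_like(x)
    if not win.enabled:
        inside = (x >= win.x_exp_min) & (x <= win.x_exp_max)
        w[inside] = 1.0
        return float(w) if w.ndim == 0 else w

    interior = (x >= win.x_int_min) & (x <= win.x_int_max)
    w[interior] = 1.0
    left = (x >= win.x_exp_min) & (x < win.x_int_min)
    if np.any(left):
        s1 = win.sigma1
        taper = (
            np.exp(-0.5 * ((x[left] - win.x_int_min) / s1) ** 2) if s1 > 0 else 0.0
        )
        w[left] = np.maximum(win.floor, taper)
    right = (x > win.x_int_max) & (x <= win.x_exp_max)
    if np.any(right):
        s2 = win.sigma2
        taper = (
            np.exp(-0.5 * ((x[right] - win.x_int_max) / s2) ** 2) if s2 > 0 else 0.0
        )
        w[right] = np.maximum(win.floor, taper)
    return float(w) if w.ndim == 0 else w


def weighted_rmsd(
    calc: ContinuousSpectrum,
    exp: ContinuousSpectrum,
    win: WeightWindow,
    normalize: bool = True,
) -> float:
    """Weighted RMSD = sqrt(Σ w_i (y_i − y_exp,i)² / Σ w_i).

    Both spectra must share a grid; by default both are max-normalised first
    so the similarity bounds (1 achiral, 2 chiral) are attainable.
    """
    if calc.grid.shape != exp.grid.shape or not np.allclose(calc.grid, exp.grid):
        raise SpectrumError("spectra must be interpolated onto a common grid")
    yc = calc.normalized().values if normalize else calc.values
    ye = exp.normalized().values if normalize else exp.values
    w = weight_function(calc.grid, win)
    wsum = w.sum()
    if wsum == 0:
        raise SpectrumError("weighting window has no overlap with the grid")
    return float(np.sqrt(np.sum(w * (yc - ye) ** 2) / wsum))


def similarity(rmsd: float, chiral: bool) -> float:
    """Similarity index S = 1 − RMSD/max, clipped to [0, 1].

    max is the largest RMSD two max-normalised spectra can reach: 1 for
    achiral (non-negative) signals, 2 for signed chiral ones.
    """
    if rmsd < 0:
        raise SpectrumError("RMSD must be non-negative")
    max_rmsd = 2.0 if chiral else 1.0
    return float(np.clip(1.0 - rmsd / max_rmsd, 0.0, 1.0))


def autoconvolute(
    impulses: list[ImpulseSpectrum],
    populations,
    exp: ContinuousSpectrum,
    win: WeightWindow | None = None,
    gamma_bounds: tuple[float, float] | None = None,
    shift_bounds: tuple[float, float] | None = None,
    kind: str | None = None,
    prescan: int = 8,
) -> FitResult:
    """Fit broadening γ and shift Δ to an experimental spectrum.

    Minimises the weighted RMSD between the Boltzmann-weighted calculated
    spectrum and the (max-normalised) experimental trace with bounded
    L-BFGS-B. The objective can be mildly multimodal in the shift when sticks
    are narrow, so a coarse ``prescan × prescan`` grid over the bounds picks
    the start (set ``prescan=0`` to start from the bound midpoints). On
    optimizer failure the last iterate is returned with ``converged=False``.
    """
    kind = kind or impulses[0].kind
    dom = _domain(kind)
    gb = gamma_bounds or DEFAULT_GAMMA_BOUNDS[dom]
    sb = shift_bounds or DEFAULT_SHIFT_BOUNDS[dom]
    if not all(np.isfinite([*gb, *sb])):
        raise SpectrumError("fit bounds must be finite")
    if win is None:
        win = WeightWindow(
            x_exp_min=float(exp.grid[0]), x_exp_max=float(exp.grid[-1]), enabled=False
        )
    exp_n = exp.normalized()
    n_eval = 0
    # optimize in unit-box coordinates: γ and Δ live on very different scales
    # (tens of cm⁻¹ vs a scaling factor near 1), which otherwise stalls the
    # quasi-Newton line search
    lo = np.array([gb[0], sb[0]])
    span = np.array([gb[1] - gb[0], sb[1] - sb[0]])
    span[span == 0] = 1.0

    def objective(u: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        gamma, shift = lo + np.asarray(u) * span
        params = ConvolutionParams(gamma=float(gamma), shift=float(shift))
        calc = ensemble_spectrum(impulses, populations, params, exp.grid)
        return weighted_rmsd(calc, exp_n, win, normalize=True)

    u0 = np.array([0.5, 0.5])
    if prescan and prescan >= 2:
        pts = np.linspace(0.0, 1.0, prescan)
        best = (np.inf, u0)
        for ug in pts:
            for us in pts:
                val = objective(np.array([ug, us]))
                if val < best[0]:
                    best = (val, np.array([ug, us]))
        u0 = best[1]

    res = minimize(
        objective,
        u0,
        method="L-BFGS-B",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        options={"ftol": 1e-15, "gtol": 1e-12, "eps": 1e-9},
    )
    gamma_opt, shift_opt = (lo + res.x * span).tolist()
    rmsd = float(res.fun)
    return FitResult(
        gamma=gamma_opt,
        shift=shift_opt,
        rmsd=rmsd,
        similarity=similarity(rmsd, chiral=kind in CHIRAL_KINDS),
        converged=bool(res.success),
        gamma_bounds=tuple(gb),
        shift_bounds=tuple(sb),
        n_evaluations=n_eval,
    )


def read_xy(path: str | Path) -> ContinuousSpectrum:
    """Read a two-column XY text file (whitespace- or comma-separated).

    Rows may be in any order; they are sorted by x and linearly interpolated
    onto a uniform grid of :data:`GRID_POINTS` points spanning the data range.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.replace(",", " ").split()
        if len(parts) < 2:
            raise SpectrumError(f"{path}:{ln}: expected two columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumError(f"{path}:{ln}: non-numeric value") from exc
    if len(rows) < 2:
        raise SpectrumError(f"{path}: need at least two data points")
    rows.sort()
    x, y = np.array(rows).T
    grid = np.linspace(x[0], x[-1], GRID_POINTS)
    return ContinuousSpectrum(grid, np.interp(grid, x, y))


def write_xy(spec: ContinuousSpectrum, path: str | Path) -> None:
    """Write a curve as two-column XY text."""
    lines = [f"{x:.6f}\t{y:.8e}" for x, y in zip(spec.grid, spec.values)]
    Path(path).write_text("\n".join(lines) + "\n")
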