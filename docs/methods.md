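# Methods

## Data model and units

A conformer is a geometry (Å) with an electronic energy E_el, optionally a
Gibbs energy G and harmonic wavenumbers, the scalar norm B of its
rotational-constant vector, a degeneracy g, a Boltzmann population, and an
active flag. Energies are held in kcal/mol throughout; rotational constants
in MHz; temperatures in K. XYZ comment lines that parse as a single real
number are treated as electronic energies in Hartree — the convention of the
common tight-binding ensemble generators — and converted with
627.5094740631 kcal/mol per Hartree. This is an assumption, not a guarantee
of the XYZ format: ensembles from other sources can carry no energy at all,
in which case the first calculation step supplies one. Atomic masses are
most-common-isotope masses (the standard convention for rotational
constants), taken from RDKit's periodic table.

Rotational constants are B_k = h/(8π²I_k) from the eigendecomposition of the
mass-weighted inertia tensor. Moments below 10⁻⁶ u·Å² are treated as zero:
linear molecules then yield two finite constants (the norm runs over the
finite components) and a single atom gets B = 0 by convention.

## Dual-filter pruning

Duplicates are detected by the conjunction |ΔE| < thrG **and** |ΔB| < thrB —
a deliberate pairwise scalar test that avoids alignment-based RMSD entirely.
The scan processes active conformers in ascending energy (ties broken by
original file index) with a greedy keep list, which makes the result
deterministic, guarantees the global minimum survives, and is idempotent;
property tests verify equivalence with a brute-force all-pairs oracle on
random ensembles up to 200 conformers. Both inequalities are strict, as is
the retention window (kept iff E − E_min < ΔG_max). Defaults: thrG = 0.05
kcal/mol and thrB = 15 MHz (CREST-like duplicate-detection settings);
ΔG_max = 6.0 kcal/mol for single-point steps and 3.5 kcal/mol for
optimisation/frequency steps — single points keep a wider window because
high-energy structures may relax substantially in a later optimisation. All
three are per-step overridable. Filtering uses G whenever every active
conformer has one (i.e. after a frequency step), otherwise E_el.

## qRRHO thermochemistry

G = E_el + ZPE + H_corr(T) − T·S_total from ideal-gas partition functions
(translation at the given pressure, rigid rotor with symmetry number σ,
harmonic oscillators). The vibrational entropy of each mode is interpolated
between the harmonic value and a free-rotor value,
S = w·S_HO + (1 − w)·S_FR with w(ν) = 1/(1 + (ν₀/ν)^α), defaults ν₀ = 100
cm⁻¹ and α = 4; the free-rotor moment μ = h/(8π²ν) is damped through an
averaging moment B_av = 10⁻⁴⁴ kg·m², which caps S_FR as ν → 0. ZPE and
thermal enthalpy remain purely harmonic — damping the entropy only is the
original choice of this interpolation scheme, and it keeps the high-frequency
limit exactly harmonic (verified to 10⁻⁶ kcal/mol at 2000 cm⁻¹). Imaginary
frequencies are dropped with a warning before any thermochemistry:
transition-state refinements legitimately carry exactly one, and it must not
enter S_vib. Degeneracies default to 1 and can be set per conformer; the
populations use R = 1.987204×10⁻³ kcal/(mol·K) and are computed with a
log-sum-exp for numerical safety.

## Clustering

Features are the descending eigenvalues of each conformer's interatomic
distance matrix — invariant under rigid motion and atom renumbering, and
optionally restricted to heavy atoms to emphasise skeletal differences. PCA
keeps components covering ≥ 95% of the variance (full SVD, deterministic up
to sign; configurable); a constant feature matrix degrades to a single zero
component with a warning. K-means runs with 10 seeded restarts per candidate
k. In automatic mode every k from max(2, ⌈0.10·n⌉) to ⌊0.80·n⌋ is evaluated
(ceil below, floor above; k = n excluded since the silhouette is undefined
there) and the highest silhouette wins, ties going to the smaller k because
a coarser reduction is cheaper downstream. The silhouette is computed in the
PCA score space — the space the clustering itself operates in. With fewer
than three active conformers clustering is skipped (every conformer its own
cluster). Each cluster is represented by its lowest-energy member, and
ΔE_av = E_av,TOT − E_av,clustered (populations recomputed over the
representatives) reports the energetic cost; it is exactly 0 at k = n and
grows as the reduction coarsens.

## Spectra

IR/VCD sticks are broadened with a Lorentzian whose peak equals the stick
intensity, L(X) = Σ I_i γ²/(γ² + 4(X − ω_iΔ)²), with a single fitted FWHM γ
for all sticks and a multiplicative frequency-scaling shift Δ. UV/ECD sticks
use a normalised Gaussian with σ = γ/(2√(2 ln 2)) and an additive shift in
nm — negative shifts move bands to shorter wavelength (blue shift). Shifts
are applied and reported in the plotting units (cm⁻¹ scaling factor / nm
offset); `enref.units.ev_fwhm_to_nm` converts energy-domain broadenings
quoted in eV. Ensemble spectra are population-weighted sums of per-conformer
curves.

Experimental traces are two-column XY text (whitespace or comma separated,
any row order), interpolated onto a 1000-point uniform grid spanning the
recorded window. Before comparison both spectra are max-normalised
(max|y| = 1); this is what makes the similarity bounds attainable — two
normalised non-negative curves differ by at most 1 in RMSD and two signed
ones by at most 2 — so S = 1 − RMSD/max lands in [0, 1]. The weighted RMSD
uses a window that is 1 in the user's region of interest, 0 outside the
experimental range, and in between follows a Gaussian taper centred at the
interior bound (σ = 0.1 × the width of the taper region) floored at 0.15, so
the optimizer still feels the band edges; disabling the window reduces it to
a step over the experimental range. The taper equals 1 at its centre, making
the window continuous at the interior bounds.

`autoconvolute` minimises the weighted RMSD over (γ, Δ) with L-BFGS-B inside
user bounds (defaults: γ ∈ [2, 24] cm⁻¹ with Δ ∈ [0.94, 1.02] for IR/VCD;
γ ∈ [5, 60] nm with Δ ∈ [−50, +50] nm for UV/ECD; initial FWHM defaults 8
cm⁻¹ / 20 nm, all overridable). Two numerical choices matter here. First,
the objective is mildly multimodal in Δ when γ is small (sticks can lock
onto the wrong neighbours), so an 8×8 coarse grid over the bounds selects
the start; setting `prescan=0` recovers a plain midpoint start. Second, the
two parameters live on scales ~300× apart, which stalls the quasi-Newton
line search; the optimisation therefore runs in unit-box-rescaled
coordinates. With both choices, noiseless synthetic experiments are
recovered to ≲0.001% in both parameters across seeds; on optimizer failure
the last iterate is returned flagged `converged=False`.

## Protocols and the calculator contract

Protocols are JSON: a `steps` array of stages with kind (single_point, opt,
freq, opt_freq), a free-text level label, solvent, charge, multiplicity,
threshold overrides, clustering and spectra settings, free-form
`extra_input` engine directives, and a per-step temperature. Validation is
strict — unknown keys are rejected with their path — and the field names are
this package's own dialect. Backends implement a four-capability contract
(energy, optimize, frequencies, spectra_impulses) with one `evaluate` call;
capability checks run before any evaluation. A failing conformer is
deactivated and listed in the summary rather than aborting the run. After
every step the surviving ensemble is written as XYZ, so a run can resume
from any checkpoint. The default temperature is 298.15 K.

## The synthetic calculator and fixtures — what they do and do not show

The synthetic calculator is a deterministic toy backend: the energy is a sum
of Morse-like pair terms over interatomic distances (hence exactly
translation/rotation invariant) with seeded per-element-pair parameters,
plus 10 kcal/mol per unit of spin multiplicity above singlet; optimisation
is bounded quasi-Newton descent on that surface (never uphill);
frequencies are eigenvalues of a pairwise-spring Hessian whose rest
configuration is the current geometry, hence positive semidefinite with the
rigid-body zeros removed; impulses reuse those frequencies with seeded
intensities. Fixture ensembles are torsionally perturbed zig-zag chains —
their rotational constants and distance-matrix eigenvalues respond to
conformational change the way real conformers' do, which is all the filters
see. None of this is chemistry: passing tests demonstrate that the
refinement logic (filtering, weighting, clustering, spectra, reporting,
determinism) is correct, not that any energy is physically meaningful, and
real ensembles bring correlated noise, near-degenerate duplicates straddling
thresholds, and basis-set/level effects the synthetic conditions do not
emulate. Engine adapters (ORCA/Gaussian-style) are deliberately out of
scope; the contract mirrors the surface they need.

## Problem sizes

Default test and acceptance runs use ensembles of 10–30 conformers of 6–10
atoms, 100 random pruning ensembles up to 200 conformers, 20
spectral-recovery fits of 12 sticks on ~1200-point grids, and three-step
protocols on 12-conformer ensembles — sizes chosen so the full suite
completes in seconds while still exercising every code path at realistic
ensemble/feature dimensionalities.

## Known limitations

- No anharmonicity, no concentration-corrected standard states, no solvation
  physics; charge/solvent fields are passed to the backend untouched.
- Comment-line Hartree interpretation is a convention, not detected.
- The duplicate filter is a heuristic: distinct conformers that coincide in
  both energy and B norm (e.g. some enantiomeric pairs) would be merged.
- UV/ECD shifts are additive in nm although electronic shifts are physically
  more natural in eV; the conversion helper covers the gap.
- K-means with Euclidean metric on PCA scores inherits K-means' convexity
  bias; alternative clusterers are out of scope.
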