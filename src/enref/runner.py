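"""Protocol execution: the refinement loop over steps.

For each step the engine evaluates every active conformer through the
calculator, refreshes the rotational-constant norms on any updated
geometries, applies qRRHO thermochemistry when frequencies are available,
prunes duplicates and the energy window, optionally clusters (keeping only
representatives), and optionally simulates/aligns spectra. Every step writes
a tab-separated report, the surviving ensemble as XYZ (a checkpoint a run can
resume from), and the run ends with a machine-readable JSON summary. Reports
contain no timestamps, so identical inputs and seed reproduce them
byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .calculators import Calculator
from .clustering import eigen_features, evaluate_clustering_loss, optimize_k, pca_reduce
from .ensemble import (
    Ensemble,
    molecular_mass,
    moments_of_inertia,
    rotational_constants,
    write_xyz_ensemble,
)
from .errors import DataError
from .protocol import ProtocolStep
from .pruning import deduplicate, energy_window
from .spectra import (
    CHIRAL_KINDS,
    ConvolutionParams,
    ImpulseSpectrum,
    VIBRATIONAL_KINDS,
    autoconvolute,
    DEFAULT_FWHM,
    ensemble_spectrum,
    read_xy,
    write_xy,
)
from .thermo import ThermoInput, boltzmann_populations, drop_imaginary, qrrho_gibbs

__all__ = ["run_protocol"]


def _evaluate_step(ens: Ensemble, step: ProtocolStep, calc: Calculator):
    """Run the calculator on each active conformer; flag failures."""
    failures = []
    impulse_store: dict[int, dict[str, ImpulseSpectrum]] = {}
    temperature = step.temperature or ens.temperature
    for conf in ens.active:
        try:
            result = calc.evaluate(step, conf)
        except Exception as exc:  # noqa: BLE001 — robustness over single failures
            conf.active = False
            failures.append({"index": conf.index, "error": str(exc)})
            continue
        conf.e_el = result.e_el
        if result.coords is not None:
            if result.coords.shape != conf.coords.shape:
                raise DataError(
                    f"calculator returned {result.coords.shape} coordinates for "
                    f"conformer {conf.index} with {conf.n_atoms} atoms"
                )
            conf.coords = np.asarray(result.coords, dtype=float)
        _, conf.b_norm = rotational_constants(conf)
        if result.frequencies is not None:
            conf.frequencies = drop_imaginary(result.frequencies)
            inp = ThermoInput(
                frequencies=conf.frequencies,
                moments_of_inertia=moments_of_inertia(conf),
                molecular_mass=molecular_mass(conf),
                temperature=temperature,
            )
            conf.gibbs = qrrho_gibbs(conf.e_el, inp).gibbs
        else:
            conf.gibbs = None
        if result.impulses:
            impulse_store[conf.index] = result.impulses
    return failures, impulse_store


def _populate(ens: Ensemble, use_gibbs: bool, temperature: float) -> None:
    active = ens.active
    energies = [c.energy(use_gibbs) for c in active]
    degens = [c.degeneracy for c in active]
    pops = boltzmann_populations(energies, degens, temperature)
    for c, p in zip(active, pops):
        c.population = float(p)
    for c in ens.conformers:
        if not c.active:
            c.population = None


def _cluster_step(ens: Ensemble, step: ProtocolStep, use_gibbs: bool, seed: int):
    settings = step.cluster
    feats = eigen_features(ens, include_hydrogens=settings.include_hydrogens)
    scores = pca_reduce(feats)
    energies = np.array([c.energy(use_gibbs) for c in ens.active])
    result = optimize_k(scores, energies, k_user=settings.k, seed=seed)
    pops = boltzmann_populations(
        energies, temperature=step.temperature or ens.temperature
    )
    loss = evaluate_clustering_loss(
        energies, pops, result, temperature=step.temperature or ens.temperature
    )
    active = ens.active
    keep = {active[i].index for i in result.representatives}
    for c in active:
        if c.index not in keep:
            c.active = False
    ens.log(
        {
            "op": "cluster",
            "k": result.k,
            "silhouette": result.silhouette,
            "delta_e_av": loss,
            "n_active": ens.n_active,
        }
    )
    return result, loss


def _spectra_step(
    ens: Ensemble,
    step: ProtocolStep,
    impulse_store: dict[int, dict[str, ImpulseSpectrum]],
    out_dir: Path,
):
    settings = step.spectra
    results = {}
    active = [c for c in ens.active if c.index in impulse_store]
    if not active:
        return results
    pops = np.array([c.population for c in active])
    pops = pops / pops.sum()
    for kind in settings.kinds:
        sets = [
            impulse_store[c.index][kind]
            for c in active
            if kind in impulse_store[c.index]
        ]
        if len(sets) != len(active):
            continue
        vib = kind in VIBRATIONAL_KINDS
        fwhm = (settings.fwhm_vibro if vib else settings.fwhm_electro) or DEFAULT_FWHM[
            "vibrational" if vib else "electronic"
        ]
        lo = min(s.positions.min() for s in sets)
        hi = max(s.positions.max() for s in sets)
        pad = 5.0 * fwhm
        grid = np.linspace(lo - pad, hi + pad, 1000)
        params = ConvolutionParams(gamma=fwhm, shift=1.0 if vib else 0.0)
        curve = ensemble_spectrum(sets, pops, params, grid)
        write_xy(curve, out_dir / f"step{step.index}_{kind}.xy")
        entry = {"kind": kind, "fwhm": fwhm}
        if settings.experimental:
            exp = read_xy(settings.experimental)
            fit = autoconvolute(sets, pops, exp, kind=kind)
            entry["fit"] = {
                "gamma": fit.gamma,
                "shift": fit.shift,
                "rmsd": fit.rmsd,
                "similarity": fit.similarity,
                "converged": fit.converged,
            }
            best = ensemble_spectrum(
                sets, pops, ConvolutionParams(fit.gamma, fit.shift), exp.grid
            )
            write_xy(best, out_dir / f"step{step.index}_{kind}_fitted.xy")
        results[kind] = entry
    return results


def _write_report(ens: Ensemble, step: ProtocolStep, out_dir: Path) -> None:
    dup_map: dict[int, int] = {}
    removed: set[int] = set()
    for entry in ens.step_log:
        if entry.get("op") == "deduplicate":
            dup_map.update(entry["duplicates"])
        elif entry.get("op") == "energy_window":
            removed.update(entry["removed"])
    lines = ["index\tE_el\tG\tB_norm\tpopulation\tstatus"]
    for c in ens.conformers:
        if c.active:
            status = "kept"
        elif c.index in dup_map:
            status = f"duplicate-of-{dup_map[c.index]}"
        elif c.index in removed:
            status = "over-window"
        else:
            status = "inactive"
        fmt = lambda v: "NA" if v is None else f"{v:.6f}"  # noqa: E731
        pop = "NA" if c.population is None else f"{c.population:.6f}"
        lines.append(
            f"{c.index}\t{fmt(c.e_el)}\t{fmt(c.gibbs)}\t{fmt(c.b_norm)}\t{pop}\t{status}"
        )
    (out_dir / f"step{step.index}_report.tsv").write_text("\n".join(lines) + "\n")


def run_protocol(
    ens: Ensemble,
    steps: list[ProtocolStep],
    calc: Calculator,
    out_dir: str | Path,
    seed: int = 0,
) -> Ensemble:
    """Execute a refinement protocol and write per-step reports.

    Capability mismatches abort before any evaluation; individual calculator
    failures deactivate the conformer and the run continues, with failures
    listed in the final summary. Returns the refined ensemble.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    required = set().union(*(s.required_capabilities() for s in steps))
    calc.check_capabilities(required)

    summary: dict = {"seed": seed, "steps": []}
    for step in steps:
        n_before = ens.n_active
        failures, impulse_store = _evaluate_step(ens, step, calc)
        use_gibbs = all(c.gibbs is not None for c in ens.active)
        thr = step.prune_thresholds()
        deduplicate(ens, thr, use_gibbs=use_gibbs)
        n_after_dedup = ens.n_active
        energy_window(ens, thr.thr_g_max, use_gibbs=use_gibbs)
        n_after_window = ens.n_active
        temperature = step.temperature or ens.temperature
        _populate(ens, use_gibbs, temperature)

        cluster_info = None
        if step.cluster and step.cluster.enabled:
            result, loss = _cluster_step(ens, step, use_gibbs, seed=seed + step.index)
            _populate(ens, use_gibbs, temperature)
            cluster_info = {
                "k": result.k,
                "silhouette": result.silhouette,
                "delta_e_av": loss,
            }

        spectra_info = None
        if step.spectra is not None:
            spectra_info = _spectra_step(ens, step, impulse_store, out_dir)

        _write_report(ens, step, out_dir)
        write_xyz_ensemble(ens, out_dir / f"step{step.index}_ensemble.xyz")
        entry = {
            "index": step.index,
            "kind": step.kind,
            "level": step.level,
            "charge": step.charge,
            "multiplicity": step.multiplicity,
            "use_gibbs": use_gibbs,
            "n_before": n_before,
            "n_after_dedup": n_after_dedup,
            "n_after_window": n_after_window,
            "n_active": ens.n_active,
            "thresholds": {
                "thr_g": thr.thr_g,
                "thr_b": thr.thr_b,
                "thr_g_max": thr.thr_g_max,
            },
            "failures": failures,
        }
        if cluster_info:
            entry["cluster"] = cluster_info
        if spectra_info:
            entry["spectra"] = spectra_info
        summary["steps"].append(entry)
        ens.log({"op": "step_done", **{k: entry[k] for k in ("index", "n_active")}})

    summary["n_final"] = ens.n_active
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return ens
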