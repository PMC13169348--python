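"""JSON protocol parsing and validation.

A protocol is a JSON document with a top-level ``steps`` array; each step
describes one refinement stage: the calculation kind (single_point, opt,
freq, opt_freq), a free-text level-of-theory label, optional solvent, charge
and spin multiplicity, optional pruning-threshold overrides, optional
clustering and spectra settings, and free-form extra engine directives.
Unknown keys are rejected with the offending path so typos cannot silently
change a run.

Example::

    {"steps": [
      {"kind": "single_point", "level": "gfn2-xtb"},
      {"kind": "opt_freq", "level": "r2scan-3c",
       "thresholds": {"thr_g": 0.05, "thr_b": 15.0},
       "cluster": {"enabled": true, "include_hydrogens": false}},
      {"kind": "single_point", "level": "wb97x-d4/def2-qzvpp"}
    ]}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .pruning import DEFAULT_WINDOWS, PruneThresholds, default_thresholds

__all__ = ["ProtocolStep", "ClusterSettings", "SpectraSettings", "ThresholdOverrides",
           "parse_protocol", "protocol_template"]

StepKind = Literal["single_point", "opt", "freq", "opt_freq"]


class ThresholdOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    thr_g: Optional[float] = Field(default=None, gt=0)
    thr_b: Optional[float] = Field(default=None, gt=0)
    thr_g_max: Optional[float] = Field(default=None, gt=0)


class ClusterSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    k: Optional[int] = Field(default=None, ge=2)  # None → silhouette-driven
    include_hydrogens: bool = True


class SpectraSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kinds: list[Literal["IR", "VCD", "UV", "ECD"]] = Field(default_factory=lambda: ["IR"])
    fwhm_vibro: Optional[float] = Field(default=None, gt=0)
    fwhm_electro: Optional[float] = Field(default=None, gt=0)
    experimental: Optional[str] = None  # path to a two-column XY file


class ProtocolStep(BaseModel):
    """One refinement stage of a protocol."""

    model_config = ConfigDict(extra="forbid")

    kind: StepKind
    level: str
    solvent: Optional[str] = None
    charge: int = 0
    multiplicity: int = Field(default=1, ge=1)
    thresholds: Optional[ThresholdOverrides] = None
    cluster: Optional[ClusterSettings] = None
    spectra: Optional[SpectraSettings] = None
    extra_input: list[str] = Field(default_factory=list)
    temperature: Optional[float] = Field(default=None, gt=0)
    index: int = 0

    def prune_thresholds(self) -> PruneThresholds:
        """Effective thresholds: step-kind defaults with user overrides."""
        ov = self.thresholds or ThresholdOverrides()
        return default_thresholds(
            self.kind, thr_g=ov.thr_g, thr_b=ov.thr_b, thr_g_max=ov.thr_g_max
        )

    def required_capabilities(self) -> set[str]:
        caps = {"energy"}
        if self.kind in ("opt", "opt_freq"):
            caps.add("optimize")
        if self.kind in ("freq", "opt_freq"):
            caps.add("frequencies")
        if self.spectra is not None:
            caps.add("spectra_impulses")
        return caps


class _Protocol(BaseModel):
    model_config = ConfigDict(extra="forbid")
    steps: list[ProtocolStep] = Field(min_length=1)


def parse_protocol(path: str | Path) -> list[ProtocolStep]:
    """Parse and validate a protocol JSON file into a list of steps."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON ({exc})") from exc
    try:
        proto = _Protocol.model_validate(doc)
    except ValidationError as exc:
        locs = "; ".join(
            "/".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"{path}: invalid protocol ({locs})") from exc
    for i, step in enumerate(proto.steps):
        step.index = i
    return proto.steps


def protocol_template() -> str:
    """A commented-free JSON template for a three-step refinement."""
    template = {
        "steps": [
            {"kind": "single_point", "level": "cheap-sp"},
            {
                "kind": "opt_freq",
                "level": "dft-opt",
                "thresholds": {"thr_g": 0.05, "thr_b": 15.0},
                "cluster": {"enabled": False, "include_hydrogens": True},
            },
            {"kind": "single_point", "level": "final-sp"},
        ]
    }
    return json.dumps(template, indent=2)


def window_for(kind: str) -> float:
    """Default retention window (kcal/mol) for a step kind."""
    if kind not in DEFAULT_WINDOWS:
        raise ConfigError(f"unknown step kind {kind!r}")
    return DEFAULT_WINDOWS[kind]
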