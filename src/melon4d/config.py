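"""Run configuration: presets, YAML parsing, validation, resolution.

A run is fully described by a :class:`RunConfig` with sections for the
grid, nucleus geometry, initial seeds, model parameters, integrator and
output.  Every parameter has a reference default (the interphase fly
nucleus setup); a YAML file only has to state deviations.  Unknown keys
are rejected with field-level messages, and a fully resolved config echo
is written into every output directory for provenance.

Presets
-------
``two-component-conventional``
    One heterochromatin field ψ1 (β_ψ1ψ2 = β_ψ2 = γ1 = γ2 = 0).
``two-component-adhesive``
    As above with lamina adhesion on (γ1 > 0), producing peripheral
    heterochromatin.
``three-component``
    fHC (ψ1) and cHC (ψ2) resolved separately: weak fHC-EC coupling,
    strong cHC-EC coupling, strong subtype demixing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dynamics import IntegratorConfig
from .geometry import DEFAULT_CT_CENTERS, NucleusGeometry, SeedLayout
from .grid import DEFAULT_EXTENTS, DEFAULT_SHAPE, SimulationGrid
from .model import ModelParameters

__all__ = ["RunConfig", "PRESETS", "load_config", "save_config",
           "ConfigError"]


class ConfigError(ValueError):
    """Configuration file is invalid or internally inconsistent."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GridSection(_Section):
    shape: Tuple[int, int, int] = DEFAULT_SHAPE
    extents: Tuple[float, float, float] = DEFAULT_EXTENTS
    boundary_mode: Literal["zero-flux", "periodic"] = "zero-flux"
    #: divide the mesh per axis (4 → quarter linear resolution)
    resolution_divisor: int = 1

    def build(self) -> SimulationGrid:
        shape = tuple(max(1, n // self.resolution_divisor)
                      for n in self.shape)
        return SimulationGrid(shape, self.extents, self.boundary_mode)


class GeometrySection(_Section):
    a: float = 2.5
    b: float = 4.0
    c: float = 1.2
    eps_eta: float = 0.04
    center: Optional[Tuple[float, float, float]] = None

    def build(self) -> NucleusGeometry:
        return NucleusGeometry(a=self.a, b=self.b, c=self.c,
                               eps_eta=self.eps_eta, center=self.center)


class SeedsSection(_Section):
    ct_centers: List[Tuple[float, float, float]] = \
        Field(default_factory=lambda: [tuple(c) for c in DEFAULT_CT_CENTERS])
    ct_radius: Optional[float] = None
    hc_core_radius: Optional[float] = None
    hc_fraction: float = 0.25
    chc_fraction: float = 0.0

    def build(self) -> SeedLayout:
        return SeedLayout(ct_centers=tuple(tuple(c) for c in self.ct_centers),
                          ct_radius=self.ct_radius,
                          hc_core_radius=self.hc_core_radius,
                          hc_fraction=self.hc_fraction,
                          chc_fraction=self.chc_fraction)


class ParametersSection(_Section):
    n_chromosomes: int = 8
    L_phi: float = 1.0
    L_psi1: float = 1.0
    L_psi2: float = 1.0
    length_scale: float = 1.0
    time_scale: float = 0.005
    D_phi: float = 20.0
    D_psi1: float = 12.0
    D_psi2: float = 12.0
    eps_phi: Optional[float] = None
    eps_psi1: Optional[float] = None
    eps_psi2: Optional[float] = None
    a1: float = 0.16
    a2: float = 2.0
    a3: float = 2.0
    a4: float = 2.0
    beta0: float = 16.7
    beta0_psi: Optional[float] = None    # None → beta0
    beta_phi: float = 40.0
    beta_psi1: float = 0.1
    beta_psi2: float = 0.0
    beta_psi1psi2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    noise_amp1: float = 5.0
    noise_amp2: float = 5.0
    nuclear_volume: Optional[float] = None   # None → analytic (4/3)πabc
    target_V: Optional[List[float]] = None
    target_v: Optional[List[float]] = None
    target_w: Optional[List[float]] = None

    @model_validator(mode="after")
    def _check_diffusion_chain(self) -> "ParametersSection":
        # the D/L/ε triple is over-determined when ε is given explicitly
        # together with a non-default D; flag it rather than guess.
        for fam, eps, D, L, D_default in (
                ("phi", self.eps_phi, self.D_phi, self.L_phi, 20.0),
                ("psi1", self.eps_psi1, self.D_psi1, self.L_psi1, 12.0),
                ("psi2", self.eps_psi2, self.D_psi2, self.L_psi2, 12.0)):
            if eps is not None and D != D_default:
                implied = L * eps**2 * self.length_scale**2 / self.time_scale
                if abs(implied - D) > 1e-9 * max(D, 1.0):
                    raise ValueError(
                        f"over-determined D/L/ε for {fam}: eps_{fam}={eps} "
                        f"implies D={implied:.4g} μm²/s via D=L·ε², but "
                        f"D_{fam}={D} was also set; drop one of them")
        return self

    def build(self, geometry: GeometrySection,
              seeds: Optional["SeedsSection"] = None) -> ModelParameters:
        data = self.model_dump()
        if data["nuclear_volume"] is None:
            data["nuclear_volume"] = geometry.build().volume
        if seeds is not None:
            # default volume targets follow the seeded HC budget and split
            data["hc_fraction"] = seeds.hc_fraction
            data["chc_split"] = seeds.chc_fraction
        return ModelParameters(**data)


class IntegratorSection(_Section):
    dt: float = 0.04
    n_steps: int = 1000
    scheme: Literal["explicit-euler", "semi-implicit-spectral"] = \
        "semi-implicit-spectral"
    rng_seed: int = 0
    snapshot_every: int = 0
    noise_on: bool = False
    energy_every: int = 1
    max_halvings: int = 12
    descent_check: bool = True

    def build(self) -> IntegratorConfig:
        return IntegratorConfig(**self.model_dump())


class OutputSection(_Section):
    directory: Optional[str] = None
    snapshot_formats: List[Literal["npz", "vti"]] = \
        Field(default_factory=lambda: ["npz"])


PresetName = Literal["two-component-conventional", "two-component-adhesive",
                     "three-component"]

#: parameter/seed overrides that define each preset
PRESETS = {
    "two-component-conventional": {
        "parameters": {"beta_psi1": 0.1, "beta_psi2": 0.0,
                       "beta_psi1psi2": 0.0, "gamma1": 0.0, "gamma2": 0.0},
        "seeds": {"chc_fraction": 0.0},
    },
    "two-component-adhesive": {
        "parameters": {"beta_psi1": 0.1, "beta_psi2": 0.0,
                       "beta_psi1psi2": 0.0, "gamma1": 1.0, "gamma2": 0.0},
        "seeds": {"chc_fraction": 0.0},
    },
    "three-component": {
        "parameters": {"beta_psi1": 0.1, "beta_psi2": 4.5,
                       "beta_psi1psi2": 4.5, "gamma1": 0.0, "gamma2": 0.0},
        "seeds": {"chc_fraction": 0.5},
    },
}


class RunConfig(_Section):
    """Fully validated run description; `.build_*` methods create the
    runtime objects."""

    preset: PresetName = "two-component-conventional"
    grid: GridSection = Field(default_factory=GridSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    seeds: SeedsSection = Field(default_factory=SeedsSection)
    parameters: ParametersSection = Field(default_factory=ParametersSection)
    integrator: IntegratorSection = Field(default_factory=IntegratorSection)
    output: OutputSection = Field(default_factory=OutputSection)

    @model_validator(mode="after")
    def _check_preset_contract(self) -> "RunConfig":
        if self.preset.startswith("two-component"):
            p = self.parameters
            bad = {k: getattr(p, k) for k in
                   ("beta_psi2", "beta_psi1psi2", "gamma2")
                   if getattr(p, k) != 0.0}
            if bad:
                raise ValueError(
                    f"preset {self.preset!r} is a two-component model; "
                    f"ψ2 couplings must stay zero but got {bad}")
            if self.seeds.chc_fraction != 0.0:
                raise ValueError(f"preset {self.preset!r} cannot seed a "
                                 "cHC core (chc_fraction must be 0)")
        return self

    # -- builders ------------------------------------------------------

    def build_grid(self) -> SimulationGrid:
        return self.grid.build()

    def build_geometry(self) -> NucleusGeometry:
        return self.geometry.build()

    def build_seeds(self) -> SeedLayout:
        return self.seeds.build()

    def build_parameters(self) -> ModelParameters:
        return self.parameters.build(self.geometry, self.seeds)

    def build_integrator(self) -> IntegratorConfig:
        return self.integrator.build()

    # -- serialization --------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"),
                              sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _apply_preset(data: dict) -> dict:
    preset = data.get("preset", "two-component-conventional")
    overrides = PRESETS.get(preset)
    if overrides is None:
        raise ConfigError(f"unknown preset {preset!r}; "
                          f"choose one of {sorted(PRESETS)}")
    merged = dict(data)
    for section, values in overrides.items():
        sec = dict(values)
        sec.update(merged.get(section, {}) or {})
        merged[section] = sec
    return merged


def load_config(path=None, text: Optional[str] = None,
                overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file (or ``text=""``) yields the preset's full default
    parameter set.  ``overrides`` (a nested dict) is applied on top of
    the file, before preset resolution.
    """
    if text is None:
        if path is None:
            raise ConfigError("either path or text is required")
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")
    if overrides:
        for section, values in overrides.items():
            if isinstance(values, dict):
                sec = dict(data.get(section, {}) or {})
                sec.update(values)
                data[section] = sec
            else:
                data[section] = values
    data = _apply_preset(data)
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:           # pydantic ValidationError
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(cfg.to_yaml())
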