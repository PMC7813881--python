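"""Parameter containers and scenario configuration.

All lengths are in micrometers, times in minutes, oxygen partial pressures
in mmHg, rates in 1/min, unless noted otherwise. The simulated tissue is a
thin 3-D slab (nominal thickness 30 um, one hepatocyte diameter) treated as
2-D: the thickness enters only through volume scalings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates an invariant."""


@dataclass
class Domain:
    """Rectangular tissue domain, [0, width] x [0, height] um."""

    width: float = 5000.0
    height: float = 5000.0
    thickness: float = 30.0  # nominal slab thickness; informational in 2-D

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("domain dimensions must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass
class TissueParams:
    """Synthetic liver tissue generation parameters.

    ``cv_density`` of 2e-6 per um^2 gives a mean hepatic lobule equivalent
    diameter near 800 um. Central veins closer than ``min_separation`` are
    iteratively merged at their midpoints. The parenchyma is a hexagonal
    lattice of tissue-patch agents (radius 15 um) at slightly compressed
    confluent spacing; a small exclusion disk keeps agents off the vein
    lumen.
    """

    cv_density: float = 2e-6          # central veins per um^2
    min_separation: float = 200.0     # um; CV pair-merge threshold
    parenchyma_radius: float = 15.0   # um
    spacing_factor: float = 0.95      # confluent spacing = 2 R * factor
    cv_exclusion_radius: float = 26.5  # um; central-vein lumen radius

    @property
    def spacing(self) -> float:
        return 2.0 * self.parenchyma_radius * self.spacing_factor


@dataclass
class TransportParams:
    """Oxygen transport coefficients and perfusion profile endpoints.

    The quasi-steady analytic profile pins intact-tissue voxels between
    ``sigma_cv`` (central vein outlet) and ``sigma_pt`` (portal inflow at the
    lobule boundary). ``U_cell`` is the per-cell uptake rate before scaling
    by cell volume over voxel volume; its default is calibrated so that
    static tumors develop a viable rim several hundred micrometers deep
    before oxygen falls below the necrotic threshold.
    """

    D: float = 1.0e5        # um^2/min, oxygen diffusion coefficient
    decay: float = 0.01     # 1/min, bulk decay
    U_cell: float = 3.5     # 1/min, per-cell uptake (pre volume scaling)
    S_cell: float = 0.0     # 1/min, per-cell secretion
    rho_star: float = 38.0  # mmHg, secretion saturation density
    sigma_H: float = 5.0    # mmHg, hypoxic/necrotic threshold
    sigma_cv: float = 38.0  # mmHg, oxygen at the central vein
    sigma_pt: float = 60.0  # mmHg, oxygen at the portal proxy (lobule edge)
    profile: str = "linear"  # analytic profile shape: linear | exponential

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ConfigurationError("diffusion coefficient must be positive")
        if min(self.decay, self.U_cell, self.S_cell) < 0:
            raise ConfigurationError("transport rates must be nonnegative")
        if not (self.sigma_pt > self.sigma_cv > self.sigma_H > 0):
            raise ConfigurationError(
                "need sigma_pt > sigma_cv > sigma_H > 0, got "
                f"{self.sigma_pt}, {self.sigma_cv}, {self.sigma_H}"
            )
        if self.profile not in ("linear", "exponential"):
            raise ConfigurationError(f"unknown profile {self.profile!r}")


@dataclass
class MechanicsParams:
    """Agent mechanics: adhesion/repulsion potentials and ECM tethering.

    ``r_E``/``r_P``/``d_max`` form the biomechanical triplet swept in the
    growth study: elastic restoring rate of displaced parenchyma (minutes
    timescale), plastic relaxation rate of the ECM anchor (hours timescale),
    and the maximum tolerated anchor displacement before the parenchyma
    agent apoptoses.
    """

    c_rep: float = 10.0         # um/min, repulsion strength
    c_adh: float = 0.4          # um/min, adhesion strength
    adh_multiplier: float = 1.25  # max adhesion distance / radius sum
    r_E: float = 0.1            # 1/min, elastic response rate
    r_P: float = 0.001          # 1/min, plastic relaxation rate
    d_max: float = 1.5          # um, maximum tolerated deformation
    p_scale: float | None = None  # pressure normalization; calibrated lazily

    def __post_init__(self) -> None:
        if self.r_E <= 0:
            raise ConfigurationError("r_E must be positive")
        if self.r_P < 0:
            raise ConfigurationError("r_P must be nonnegative")
        if self.d_max <= 0:
            raise ConfigurationError("d_max must be positive")
        if self.c_rep <= 0 or self.c_adh < 0:
            raise ConfigurationError("potential coefficients out of range")


#: Table of low/medium/high values swept for the biomechanics investigation.
SWEEP_GRID = {
    "r_E": (0.05, 0.1, 0.2),
    "r_P": (0.0005, 0.001, 0.002),
    "d_max": (0.75, 1.5, 3.0),
}


@dataclass
class PhenotypeParams:
    """Cell cycle, death, and volume model parameters.

    The cycle is the Ki67-advanced model: quiescent Ki67- cells enter a
    premitotic Ki67+ phase at an oxygen- and pressure-dependent rate, grow
    toward double volume over ``T_K1``, divide, and the daughters spend
    ``T_K2`` in a postmitotic Ki67+ phase before returning to Ki67-. Default
    cycle timings follow the standard breast-epithelium calibration of the
    reference agent-based framework (mean Ki67- dwell 3.62 h, premitotic
    13 h, postmitotic 2.5 h).
    """

    r01_max: float = 1.0 / (3.62 * 60.0)  # 1/min, max Ki67- -> Ki67+ rate
    T_K1: float = 13.0 * 60.0    # min, premitotic Ki67+ duration
    T_K2: float = 2.5 * 60.0     # min, postmitotic Ki67+ duration
    p1: float = 0.0              # lower pressure threshold
    p2: float = 1.0              # arrest pressure threshold
    sigma_H: float = 5.0         # mmHg, hypoxic threshold
    sigma_sat: float = 38.0      # mmHg, proliferation-saturating oxygen
    r_N_max: float = 1.0 / (6.0 * 60.0)  # 1/min, max necrosis rate
    T_apop: float = 8.6 * 60.0   # min, apoptotic shrink duration
    T_lysis: float = 6.0 * 60.0  # min, necrotic shrink duration
    tumor_radius: float = 8.4    # um, resting tumor cell radius

    def __post_init__(self) -> None:
        if self.p2 <= self.p1:
            raise ConfigurationError("need p2 > p1")
        if self.sigma_sat <= self.sigma_H:
            raise ConfigurationError("need sigma_sat > sigma_H")
        for name in ("r01_max", "T_K1", "T_K2", "r_N_max", "T_apop", "T_lysis"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


@dataclass
class SeedingSpec:
    """Tumor seeding: one cell at the domain center, or static disks.

    ``mode == "single"`` places a single quiescent tumor cell at the domain
    center. ``mode == "disks"`` fills disks (diameters in um; centers in um
    or None for an automatic non-overlapping layout) with confluent tumor
    cells flagged static — mechanics, cycling and necrosis disabled — for
    the steady-state oxygenation study.
    """

    mode: str = "single"  # "single" | "disks"
    diameters: Sequence[float] = ()
    centers: Sequence[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("single", "disks"):
            raise ConfigurationError(f"unknown seeding mode {self.mode!r}")
        if self.mode == "disks" and len(self.diameters) == 0:
            raise ConfigurationError("disk seeding needs at least one diameter")


@dataclass
class ParameterEvent:
    """Scheduled change of the biomechanical triplet at ``time_min``."""

    time_min: float
    mechanics: MechanicsParams


@dataclass
class ScenarioConfig:
    """Complete description of one simulation run."""

    domain: Domain = field(default_factory=Domain)
    tissue: TissueParams = field(default_factory=TissueParams)
    transport: TransportParams = field(default_factory=TransportParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    seeding: SeedingSpec = field(default_factory=SeedingSpec)
    duration_days: float = 90.0
    dx: float = 20.0             # um, voxel edge
    dt_diff: float = 0.01        # min, diffusion step
    dt_mech: float = 0.1         # min, mechanics step
    dt_phen: float = 6.0         # min, phenotype (macro) step
    diffusion_substeps: int | None = None  # None: dt_phen / dt_diff
    snapshot_interval: float = 360.0  # min between saved outputs
    burn_in_min: float = 60.0    # mechanics-only relaxation before seeding
    seed: int = 0
    events: Sequence[ParameterEvent] = ()

    def __post_init__(self) -> None:
        if not (0 < self.dt_diff <= self.dt_mech <= self.dt_phen):
            raise ConfigurationError("need 0 < dt_diff <= dt_mech <= dt_phen")
        if self.snapshot_interval % self.dt_phen != 0:
            raise ConfigurationError(
                "snapshot interval must be a multiple of dt_phen"
            )
        if self.dx <= 0:
            raise ConfigurationError("voxel edge must be positive")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["events"] = [dataclasses.asdict(e) for e in self.events]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        sub = {
            "domain": Domain,
            "tissue": TissueParams,
            "transport": TransportParams,
            "mechanics": MechanicsParams,
            "phenotype": PhenotypeParams,
            "seeding": SeedingSpec,
        }
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "seeding" in d and d["seeding"].centers is not None:
            d["seeding"].centers = [tuple(c) for c in d["seeding"].centers]
        events = []
        for e in d.get("events", ()):
            if isinstance(e, dict):
                mech = e["mechanics"]
                if isinstance(mech, dict):
                    mech = MechanicsParams(**mech)
                events.append(ParameterEvent(e["time_min"], mech))
            else:
                events.append(e)
        d["events"] = events
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
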