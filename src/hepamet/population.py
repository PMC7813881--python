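"""Struct-of-arrays container for cell agents.

Two agent types live here: individual tumor cells and coarse-grained
parenchyma tissue patches. Parenchyma agents carry an ECM anchor point;
tumor cells never do. Volumes follow the thin-slab convention
``V = pi R^2 * thickness`` so that radius and volume stay consistent in 2-D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# agent types
TYPE_PARENCHYMA = 0
TYPE_TUMOR = 1

# phases (dead phases never re-enter the cycle)
PHASE_KI67_NEG = 0   # quiescent
PHASE_KI67_PRE = 1   # premitotic Ki67+
PHASE_KI67_POST = 2  # postmitotic Ki67+
PHASE_APOPTOTIC = 3
PHASE_NECROTIC = 4

VIABLE_PHASES = (PHASE_KI67_NEG, PHASE_KI67_PRE, PHASE_KI67_POST)

PHASE_NAMES = {
    PHASE_KI67_NEG: "Ki67-",
    PHASE_KI67_PRE: "Ki67+pre",
    PHASE_KI67_POST: "Ki67+post",
    PHASE_APOPTOTIC: "apoptotic",
    PHASE_NECROTIC: "necrotic",
}


def radius_from_volume(volume: np.ndarray, thickness: float) -> np.ndarray:
    return np.sqrt(np.maximum(volume, 0.0) / (np.pi * thickness))


def volume_from_radius(radius: np.ndarray, thickness: float) -> np.ndarray:
    return np.pi * np.asarray(radius, dtype=float) ** 2 * thickness


@dataclass
class CellPopulation:
    """All agents of a simulation as parallel numpy arrays."""

    thickness: float = 30.0
    ids: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    type: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int8))
    phase: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int8))
    phase_clock: np.ndarray = field(default_factory=lambda: np.zeros(0))
    position: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    volume: np.ndarray = field(default_factory=lambda: np.zeros(0))
    resting_volume: np.ndarray = field(default_factory=lambda: np.zeros(0))
    target_volume: np.ndarray = field(default_factory=lambda: np.zeros(0))
    pressure: np.ndarray = field(default_factory=lambda: np.zeros(0))
    oxygen: np.ndarray = field(default_factory=lambda: np.zeros(0))
    anchor: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    static: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    next_id: int = 0
    parenchyma_apoptosis_count: int = 0  # cumulative, survives removals

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def radius(self) -> np.ndarray:
        return radius_from_volume(self.volume, self.thickness)

    @property
    def deformation(self) -> np.ndarray:
        """Anchor displacement ``d_i`` (um); NaN for tumor cells."""
        return np.linalg.norm(self.anchor - self.position, axis=1)

    # -- masks ------------------------------------------------------------

    @property
    def is_tumor(self) -> np.ndarray:
        return self.type == TYPE_TUMOR

    @property
    def is_parenchyma(self) -> np.ndarray:
        return self.type == TYPE_PARENCHYMA

    @property
    def is_viable(self) -> np.ndarray:
        return self.phase < PHASE_APOPTOTIC

    # -- editing ----------------------------------------------------------

    def add(
        self,
        positions: np.ndarray,
        cell_type: int,
        radius: float | np.ndarray,
        phase: int = PHASE_KI67_NEG,
        static: bool = False,
        anchored: bool = False,
    ) -> np.ndarray:
        """Append agents; returns their ids."""
        positions = np.asarray(positions, dtype=float).reshape(-1, 2)
        n = len(positions)
        vol = volume_from_radius(np.broadcast_to(radius, n), self.thickness)
        new_ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += n
        anchor = positions.copy() if anchored else np.full((n, 2), np.nan)
        self.ids = np.concatenate([self.ids, new_ids])
        self.type = np.concatenate([self.type, np.full(n, cell_type, np.int8)])
        self.phase = np.concatenate([self.phase, np.full(n, phase, np.int8)])
        self.phase_clock = np.concatenate([self.phase_clock, np.zeros(n)])
        self.position = np.vstack([self.position, positions])
        self.volume = np.concatenate([self.volume, vol])
        self.resting_volume = np.concatenate([self.resting_volume, vol.copy()])
        self.target_volume = np.concatenate([self.target_volume, vol.copy()])
        self.pressure = np.concatenate([self.pressure, np.zeros(n)])
        self.oxygen = np.concatenate([self.oxygen, np.zeros(n)])
        self.anchor = np.vstack([self.anchor, anchor])
        self.static = np.concatenate([self.static, np.full(n, static, bool)])
        return new_ids

    def remove(self, mask: np.ndarray) -> None:
        keep = ~np.asarray(mask, dtype=bool)
        for name in (
            "ids",
            "type",
            "phase",
            "phase_clock",
            "volume",
            "resting_volume",
            "target_volume",
            "pressure",
            "oxygen",
            "static",
        ):
            setattr(self, name, getattr(self, name)[keep])
        self.position = self.position[keep]
        self.anchor = self.anchor[keep]

    def copy(self) -> "CellPopulation":
        out = CellPopulation(thickness=self.thickness)
        for name in (
            "ids",
            "type",
            "phase",
            "phase_clock",
            "position",
            "volume",
            "resting_volume",
            "target_volume",
            "pressure",
            "oxygen",
            "anchor",
            "static",
        ):
            setattr(out, name, getattr(self, name).copy())
        out.next_id = self.next_id
        out.parenchyma_apoptosis_count = self.parenchyma_apoptosis_count
        return out
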