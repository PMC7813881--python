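"""Cell cycle, death, and volume dynamics.

Tumor cells follow the Ki67-advanced cycle: quiescent Ki67- cells enter a
premitotic Ki67+ phase at rate

    r01(sigma, p) = r01_max * clamp((sigma - sigma_H)/(sigma_sat - sigma_H))
                    * min{1, max{(p2 - p)/(p2 - p1), 0}}

(cycle entry needs oxygen above the hypoxic threshold and is arrested
entirely at pressures above p2), grow toward double volume over ``T_K1``,
divide into two postmitotic Ki67+ daughters that return to Ki67- after
``T_K2``. Below the hypoxic threshold a stochastic necrosis rate ramps
linearly up to ``r_N_max`` at zero oxygen. Dead cells shrink exponentially
(apoptotic over ``T_apop``, necrotic over ``T_lysis``) and are removed once
below 5% of resting volume; shrinking necrotic cells act as a local
pressure release. Parenchyma agents never cycle; they apoptose only through
the mechanical strain rule.
"""

from __future__ import annotations

import numpy as np

from hepamet.params import PhenotypeParams
from hepamet.population import (
    PHASE_APOPTOTIC,
    PHASE_KI67_NEG,
    PHASE_KI67_POST,
    PHASE_KI67_PRE,
    PHASE_NECROTIC,
    CellPopulation,
)

#: exponential-relaxation rate multiplier: e^-3 < 5% residual over a duration
_RELAX_FOLDS = 3.0
#: dead cells are removed below this fraction of resting volume
_REMOVAL_FRACTION = 0.05


def oxygen_multiplier(sigma: np.ndarray, params: PhenotypeParams) -> np.ndarray:
    """Linear oxygen ramp for cycle entry, clamped to [0, 1]."""
    s = np.asarray(sigma, dtype=float)
    return np.clip((s - params.sigma_H) / (params.sigma_sat - params.sigma_H), 0.0, 1.0)


def pressure_multiplier(p: np.ndarray, params: PhenotypeParams) -> np.ndarray:
    """Mechanosensory arrest factor: 1 below p1, 0 at and above p2."""
    pp = np.asarray(p, dtype=float)
    return np.clip((params.p2 - pp) / (params.p2 - params.p1), 0.0, 1.0)


def cycle_entry_rate(
    sigma: np.ndarray, p: np.ndarray, params: PhenotypeParams
) -> np.ndarray:
    """Ki67- to Ki67+ transition rate (1/min), oxygen- and pressure-gated."""
    return params.r01_max * oxygen_multiplier(sigma, params) * pressure_multiplier(p, params)


def necrosis_rate(sigma: np.ndarray, params: PhenotypeParams) -> np.ndarray:
    """Stochastic necrosis rate: linear ramp below the hypoxic threshold."""
    s = np.asarray(sigma, dtype=float)
    return params.r_N_max * np.clip((params.sigma_H - s) / params.sigma_H, 0.0, 1.0)


def advance_phase(
    pop: CellPopulation,
    dt: float,
    params: PhenotypeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance cycle phases of live, non-static tumor cells by ``dt``.

    Returns the indices of cells that completed the premitotic phase and
    must divide now. Uses the cells' stored ``oxygen`` and ``pressure``.
    """
    active = pop.is_tumor & pop.is_viable & ~pop.static
    idx = np.where(active)[0]
    if len(idx) == 0:
        return idx
    pop.phase_clock[idx] += dt

    quiescent = idx[pop.phase[idx] == PHASE_KI67_NEG]
    if len(quiescent):
        r01 = cycle_entry_rate(pop.oxygen[quiescent], pop.pressure[quiescent], params)
        enter = rng.random(len(quiescent)) < 1.0 - np.exp(-r01 * dt)
        starters = quiescent[enter]
        pop.phase[starters] = PHASE_KI67_PRE
        pop.phase_clock[starters] = 0.0
        pop.target_volume[starters] = 2.0 * pop.resting_volume[starters]

    pre = idx[(pop.phase[idx] == PHASE_KI67_PRE)]
    dividing = pre[pop.phase_clock[pre] >= params.T_K1]

    post = idx[pop.phase[idx] == PHASE_KI67_POST]
    done = post[pop.phase_clock[post] >= params.T_K2]
    pop.phase[done] = PHASE_KI67_NEG
    pop.phase_clock[done] = 0.0
    pop.target_volume[done] = pop.resting_volume[done]
    return dividing


def necrosis_check(
    pop: CellPopulation,
    dt: float,
    params: PhenotypeParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic necrosis entry for hypoxic live tumor cells.

    Returns the indices that entered necrosis this step.
    """
    active = pop.is_tumor & pop.is_viable & ~pop.static
    idx = np.where(active)[0]
    if len(idx) == 0:
        return idx
    r_n = necrosis_rate(pop.oxygen[idx], params)
    hit = idx[rng.random(len(idx)) < 1.0 - np.exp(-r_n * dt)]
    pop.phase[hit] = PHASE_NECROTIC
    pop.phase_clock[hit] = 0.0
    pop.target_volume[hit] = 0.0
    return hit


def trigger_apoptosis(pop: CellPopulation, indices: np.ndarray) -> None:
    """Send cells into the apoptotic shrink phase."""
    pop.phase[indices] = PHASE_APOPTOTIC
    pop.phase_clock[indices] = 0.0
    pop.target_volume[indices] = 0.0


def update_volume(pop: CellPopulation, dt: float, params: PhenotypeParams) -> None:
    """Exponential volume relaxation toward each cell's target volume.

    Premitotic cells relax toward double resting volume over ``T_K1``;
    apoptotic and necrotic cells shrink toward zero over ``T_apop`` and
    ``T_lysis``. Resting cells with volume at target are untouched.
    """
    tau = np.full(len(pop), np.inf)
    tau[pop.phase == PHASE_KI67_PRE] = params.T_K1 / _RELAX_FOLDS
    tau[pop.phase == PHASE_APOPTOTIC] = params.T_apop / _RELAX_FOLDS
    tau[pop.phase == PHASE_NECROTIC] = params.T_lysis / _RELAX_FOLDS
    active = np.isfinite(tau) & ~pop.static
    if not active.any():
        return
    decay = np.exp(-dt / tau[active])
    pop.volume[active] = pop.target_volume[active] + (
        pop.volume[active] - pop.target_volume[active]
    ) * decay


def remove_dead(pop: CellPopulation) -> int:
    """Remove fully shrunk dead cells; returns how many were removed."""
    gone = (~pop.is_viable) & (pop.volume < _REMOVAL_FRACTION * pop.resting_volume)
    n = int(gone.sum())
    if n:
        pop.remove(gone)
    return n


def divide(
    pop: CellPopulation, indices: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Split each listed cell into two Ki67+ postmitotic daughters.

    Daughters are placed symmetrically about the mother center along a
    random axis with separation equal to the mother radius, each carrying
    half the mother volume (total volume conserved at the division instant).
    The mother record becomes one daughter; the other is appended with a
    fresh id. Returns the ids of the appended daughters.
    """
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        return np.zeros(0, dtype=np.int64)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=len(indices))
    axis = np.column_stack([np.cos(theta), np.sin(theta)])
    mother_pos = pop.position[indices].copy()
    mother_radius = pop.radius[indices]
    mother_vol = pop.volume[indices].copy()
    offset = 0.5 * mother_radius[:, None] * axis

    # mother becomes daughter 1 in place
    pop.position[indices] = mother_pos + offset
    pop.volume[indices] = 0.5 * mother_vol
    pop.phase[indices] = PHASE_KI67_POST
    pop.phase_clock[indices] = 0.0
    pop.target_volume[indices] = pop.resting_volume[indices]

    # daughter 2 appended
    half_vol = 0.5 * mother_vol
    from hepamet.population import TYPE_TUMOR, radius_from_volume

    new_ids = pop.add(
        mother_pos - offset,
        TYPE_TUMOR,
        radius=radius_from_volume(half_vol, pop.thickness),
        phase=PHASE_KI67_POST,
    )
    tail = slice(len(pop) - len(indices), len(pop))
    pop.volume[tail] = half_vol
    pop.resting_volume[tail] = pop.resting_volume[indices]
    pop.target_volume[tail] = pop.resting_volume[indices]
    pop.oxygen[tail] = pop.oxygen[indices]
    pop.pressure[tail] = pop.pressure[indices]
    return new_ids
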