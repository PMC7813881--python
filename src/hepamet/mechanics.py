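"""Off-lattice agent mechanics.

Cells move under an inertialess force balance: pairwise adhesion/repulsion
potentials give velocity contributions directly, parenchyma agents feel an
additional elastic pull toward their ECM anchor (rate ``r_E``), and the
anchor itself creeps toward the displaced agent at the slower plastic rate
``r_P``. A parenchyma agent whose anchor displacement exceeds ``d_max``
undergoes apoptosis.

The dimensionless compressive pressure is the sum of squared repulsive
overlaps, normalized so that a cell with 12 equal neighbors at confluent
spacing in a dense 3-D packing reads exactly 1 (hence 6 neighbors in a 2-D
dense packing read 0.5). Confluent spacing is the adhesion-repulsion
equilibrium spacing, found once by root bracketing.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from hepamet.params import ConfigurationError, MechanicsParams
from hepamet.population import CellPopulation

#: fraction of a cell radius a single mechanics step may move an agent
STEP_CAP_FRACTION = 0.25


# ---------------------------------------------------------------------------
# neighbor search

def neighbor_pairs(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """All unordered index pairs with center distance < cutoff, each once.

    Uses a k-d tree; equivalent to the O(n^2) scan (coincident centers
    included: their distance 0 is below any positive cutoff).
    """
    pts = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        return np.zeros((0, 2), dtype=np.intp)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    # query_pairs uses d <= r; trim exact-cutoff ties to match d < cutoff
    if len(pairs):
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    # canonical order keeps force accumulation bit-reproducible across
    # cache rebuilds (np.add.at is order-sensitive in floating point)
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return pairs


def interaction_cutoff(params: MechanicsParams, max_radius: float) -> float:
    """Largest center distance at which two agents can interact."""
    return params.adh_multiplier * 2.0 * max_radius


# ---------------------------------------------------------------------------
# pair potentials

def _pair_speed(
    d: np.ndarray, r_rep: np.ndarray, r_adh: np.ndarray, params: MechanicsParams
) -> np.ndarray:
    """Signed speed along the separation axis (positive = repulsive)."""
    rep = params.c_rep * np.maximum(1.0 - d / r_rep, 0.0) ** 2
    adh = params.c_adh * np.maximum(1.0 - d / r_adh, 0.0) ** 2
    return rep - adh


def pair_velocity(
    pos_i: np.ndarray,
    pos_j: np.ndarray,
    radius_i: float,
    radius_j: float,
    params: MechanicsParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity contributions (um/min) on cells i and j; equal and opposite.

    Repulsion acts for d < R_i + R_j, adhesion for
    d < adh_multiplier (R_i + R_j). Coincident centers are separated along a
    seeded random direction.
    """
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    dvec = pos_i - pos_j
    d = float(np.hypot(*dvec))
    if d < 1e-12:
        rng = rng or np.random.default_rng(0)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        unit = np.array([np.cos(theta), np.sin(theta)])
        speed = params.c_rep  # full overlap: maximal repulsion
        return speed * unit, -speed * unit
    unit = dvec / d
    r_rep = radius_i + radius_j
    r_adh = params.adh_multiplier * r_rep
    speed = float(_pair_speed(np.array(d), np.array(r_rep), np.array(r_adh), params))
    return speed * unit, -speed * unit


def equilibrium_spacing_ratio(params: MechanicsParams) -> float:
    """d_eq / (R_i + R_j): adhesion-repulsion force balance, radius free.

    Solves c_rep (1 - x)^2 = c_adh (1 - x / m)^2 for x in (0, 1) with
    m = adh_multiplier; the balance depends only on the distance relative to
    the radius sum, so one root serves all radius combinations.
    """
    if params.c_adh <= 0:
        return 1.0  # no adhesion: contact at exactly the radius sum
    m = params.adh_multiplier

    def f(x: float) -> float:
        return params.c_rep * (1 - x) ** 2 - params.c_adh * (1 - x / m) ** 2

    return float(brentq(f, 1e-9, 1.0 - 1e-12))


def calibrate_pressure_scale(params: MechanicsParams) -> float:
    """Normalization so 12 confluent 3-D neighbors give pressure exactly 1."""
    phi = equilibrium_spacing_ratio(params)
    if phi >= 1.0:
        raise ConfigurationError(
            "confluent spacing reaches the repulsion range; cannot calibrate"
        )
    return 12.0 * (1.0 - phi) ** 2


def ensure_pressure_scale(params: MechanicsParams) -> float:
    if params.p_scale is None:
        params.p_scale = calibrate_pressure_scale(params)
    return params.p_scale


def simple_pressure(
    radius: float,
    neighbor_distances: np.ndarray,
    neighbor_radii: np.ndarray,
    params: MechanicsParams,
) -> float:
    """Normalized compressive pressure on one cell from its neighbors."""
    p_scale = ensure_pressure_scale(params)
    d = np.asarray(neighbor_distances, dtype=float)
    r_rep = radius + np.asarray(neighbor_radii, dtype=float)
    terms = np.maximum(1.0 - d / r_rep, 0.0) ** 2
    return float(terms.sum() / p_scale)


def compute_pressures(
    positions: np.ndarray,
    radii: np.ndarray,
    params: MechanicsParams,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell pressure from summed repulsive overlaps (vectorized)."""
    p_scale = ensure_pressure_scale(params)
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    radii = np.asarray(radii, dtype=float)
    n = len(positions)
    if pairs is None:
        pairs = neighbor_pairs(positions, interaction_cutoff(params, radii.max() if n else 1.0))
    p = np.zeros(n)
    if len(pairs) == 0:
        return p
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(positions[i] - positions[j], axis=1)
    r_rep = radii[i] + radii[j]
    terms = np.maximum(1.0 - d / r_rep, 0.0) ** 2
    np.add.at(p, i, terms)
    np.add.at(p, j, terms)
    return p / p_scale


# ---------------------------------------------------------------------------
# elasto-plastic ECM tethering

def elastic_velocity(
    positions: np.ndarray, anchors: np.ndarray, r_E: float
) -> np.ndarray:
    """Restoring velocity ``r_E (x_ECM - x_i)`` toward the anchor (um/min)."""
    return r_E * (np.asarray(anchors, dtype=float) - np.asarray(positions, dtype=float))


def relax_anchor(
    anchors: np.ndarray, positions: np.ndarray, dt: float, r_P: float
) -> np.ndarray:
    """Plastic creep of the anchor toward the agent, exact over ``dt``.

    Integrates d x_ECM/dt = r_P (x_i - x_ECM) holding x_i fixed:
    the anchor-agent separation decays by exp(-r_P dt).
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    anchors = np.asarray(anchors, dtype=float)
    positions = np.asarray(positions, dtype=float)
    decay = np.exp(-r_P * dt)
    return positions + (anchors - positions) * decay


def strain_death_check(deformation: np.ndarray, params: MechanicsParams) -> np.ndarray:
    """Apoptosis trigger: deformation strictly above ``d_max``."""
    return np.asarray(deformation, dtype=float) > params.d_max


# ---------------------------------------------------------------------------
# motion integration

def pair_velocities_bulk(
    positions: np.ndarray,
    radii: np.ndarray,
    pairs: np.ndarray,
    params: MechanicsParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Summed pairwise velocity per agent for a fixed pair list."""
    n = len(positions)
    vel = np.zeros((n, 2))
    if len(pairs) == 0:
        return vel
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = positions[i] - positions[j]
    d = np.linalg.norm(dvec, axis=1)
    zero = d < 1e-12
    if zero.any():
        rng = rng or np.random.default_rng(0)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=int(zero.sum()))
        dvec[zero] = np.column_stack([np.cos(theta), np.sin(theta)]) * 1e-12
        d[zero] = 1e-12
    unit = dvec / d[:, None]
    r_rep = radii[i] + radii[j]
    r_adh = params.adh_multiplier * r_rep
    speed = _pair_speed(d, r_rep, r_adh, params)
    speed[zero] = params.c_rep
    contrib = speed[:, None] * unit
    np.add.at(vel, i, contrib)
    np.add.at(vel, j, -contrib)
    return vel


def motion_step(
    pop: CellPopulation,
    pairs: np.ndarray,
    params: MechanicsParams,
    dt: float,
    rng: np.random.Generator | None = None,
) -> float:
    """One mechanics step; returns the max displacement (um).

    Pairwise adhesion/repulsion advances positions by forward Euler. The
    stiff elastic tether and the plastic anchor creep are then applied as
    exact exponential relaxations (an exponential integrator), so an
    isolated anchored agent matches the closed-form decays exactly. Static
    agents keep their positions (they still repel their neighbors).
    Per-step pair displacement is capped at a quarter radius; a raw
    displacement exceeding one full radius aborts with a stability
    diagnostic.
    """
    radii = pop.radius
    vel = pair_velocities_bulk(pop.position, radii, pairs, params, rng)

    disp = vel * dt
    norm = np.linalg.norm(disp, axis=1)
    movable = ~pop.static
    if np.any(norm[movable] > radii[movable]):
        worst = float(np.max(norm[movable] / np.maximum(radii[movable], 1e-12)))
        raise RuntimeError(
            "mechanics unstable: step displacement reached "
            f"{worst:.2f} cell radii; reduce dt_mech"
        )
    cap = STEP_CAP_FRACTION * radii
    over = norm > cap
    if over.any():
        disp[over] *= (cap[over] / norm[over])[:, None]
    disp[~movable] = 0.0
    pop.position = pop.position + disp

    par = pop.is_parenchyma & pop.is_viable & ~pop.static
    if par.any():
        # exact relaxation toward the anchor, then plastic creep of the anchor
        decay = np.exp(-params.r_E * dt)
        before = pop.position[par].copy()
        pop.position[par] = pop.anchor[par] + (pop.position[par] - pop.anchor[par]) * decay
        disp[par] += pop.position[par] - before
        pop.anchor[par] = relax_anchor(
            pop.anchor[par], pop.position[par], dt, params.r_P
        )
    moved = np.linalg.norm(disp, axis=1)
    return float(moved.max()) if len(moved) else 0.0
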