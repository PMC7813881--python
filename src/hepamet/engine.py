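"""Simulation orchestration: time stepping, seeding, and study protocols.

A macro-step of ``dt_phen`` minutes proceeds as: refresh permanently
disrupted voxels from tumor positions; advance the oxygen field in implicit
sub-steps; advance agent mechanics in sub-steps (static cells never move);
recompute pressures; then run the phenotype updates (cycle entry, necrosis,
volume change, division, strain-triggered parenchyma death). Diffusion runs
before mechanics before phenotype so that phenotype decisions always see
the freshest oxygen and pressure.

The three published experiment protocols are provided as functions:
:func:`run_oxygen_study` (static tumor disks solved to steady state),
:func:`run_growth_sweep` (the r_E x r_P x d_max parameter sweep), and
:func:`run_reawakening` (growth to dormancy, then three branches resumed
from one checkpoint under altered parenchyma biomechanics).
"""

from __future__ import annotations

import itertools
import pickle
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from hepamet import mechanics, perfusion, phenotype
from hepamet.params import (
    ConfigurationError,
    MechanicsParams,
    ScenarioConfig,
    SeedingSpec,
)
from hepamet.perfusion import CellSources, SubstrateField
from hepamet.population import (
    TYPE_PARENCHYMA,
    TYPE_TUMOR,
    CellPopulation,
    volume_from_radius,
)
from hepamet.rng import rng_stream
from hepamet.tissue_gen import Tissue, generate_tissue

CHECKPOINT_FORMAT = "hepamet-checkpoint"
CHECKPOINT_VERSION = 1

#: Verlet skin (um) added to the interaction cutoff when caching pairs
_PAIR_SKIN = 4.0


@dataclass
class SimulationState:
    """Complete, serializable state of one simulation run."""

    config: ScenarioConfig
    tissue: Tissue
    pop: CellPopulation
    field: SubstrateField
    clock: float = 0.0
    mechanics_params: MechanicsParams = None  # current (may differ after events)
    rng_sim: np.random.Generator = None
    rng_div: np.random.Generator = None
    rng_tie: np.random.Generator = None
    metrics: list = field(default_factory=list)
    # pair cache (not part of the logical state; rebuilt on demand)
    _pairs: np.ndarray | None = field(default=None, repr=False, compare=False)
    _pair_positions: np.ndarray | None = field(default=None, repr=False, compare=False)
    _pair_radii: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __getstate__(self):
        d = dict(self.__dict__)
        d["_pairs"] = None
        d["_pair_positions"] = None
        d["_pair_radii"] = None
        return d

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics)


# ---------------------------------------------------------------------------
# initialization and seeding

def _hex_disk(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice points within ``radius`` of ``center``."""
    dy = spacing * np.sqrt(3.0) / 2.0
    half_rows = int(np.ceil(radius / dy)) + 1
    pts = []
    for j in range(-half_rows, half_rows + 1):
        y = j * dy
        x0 = 0.5 * spacing if j % 2 else 0.0
        half_cols = int(np.ceil(radius / spacing)) + 1
        xs = x0 + spacing * np.arange(-half_cols, half_cols + 1)
        keep = xs**2 + y**2 <= radius**2
        pts.append(np.column_stack([xs[keep], np.full(keep.sum(), y)]))
    out = np.vstack(pts) + np.asarray(center, dtype=float)
    return out


def default_disk_layout(
    domain, diameters: list[float], margin: float = 150.0
) -> list[tuple[float, float]]:
    """Deterministic non-overlapping layout for static tumor disks.

    Disks are interleaved large/small and placed on a grid; raises if the
    domain cannot host them with the requested clearance.
    """
    order = np.argsort(diameters)[::-1]
    interleaved: list[int] = []
    lo, hi = 0, len(order) - 1
    while lo <= hi:
        interleaved.append(order[lo])
        if lo != hi:
            interleaved.append(order[hi])
        lo += 1
        hi -= 1
    n = len(diameters)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    xs = (np.arange(cols) + 0.5) * domain.width / cols
    ys = (np.arange(rows) + 0.5) * domain.height / rows
    centers = [None] * n
    for slot, disk_idx in enumerate(interleaved):
        r, c = divmod(slot, cols)
        centers[disk_idx] = (float(xs[c]), float(ys[r]))
    _validate_disks(domain, diameters, centers, margin)
    return centers


def _validate_disks(domain, diameters, centers, margin: float = 0.0) -> None:
    for d, (cx, cy) in zip(diameters, centers):
        r = 0.5 * d
        if cx - r < 0 or cy - r < 0 or cx + r > domain.width or cy + r > domain.height:
            raise ConfigurationError(
                f"tumor disk (d={d} um at {cx:.0f},{cy:.0f}) extends outside the domain"
            )
    arr = np.asarray(centers, dtype=float)
    rad = 0.5 * np.asarray(diameters, dtype=float)
    for i in range(len(arr)):
        for j in range(i + 1, len(arr)):
            if np.linalg.norm(arr[i] - arr[j]) < rad[i] + rad[j] + margin:
                raise ConfigurationError(f"tumor disks {i} and {j} overlap")


def seed_tumor(
    state: SimulationState, spec: SeedingSpec, rng: np.random.Generator
) -> SimulationState:
    """Place tumor cells per the seeding spec and disrupt their voxels.

    Single-cell mode puts one quiescent tumor cell at the domain center and
    removes any parenchyma agent it overlaps. Disk mode fills each disk with
    confluent, *static* tumor cells and removes the parenchyma inside.
    """
    pop = state.pop
    cfg = state.config
    r_t = cfg.phenotype.tumor_radius
    if spec.mode == "single":
        center = np.array([cfg.domain.width / 2.0, cfg.domain.height / 2.0])
        par = pop.is_parenchyma
        d = np.linalg.norm(pop.position - center, axis=1)
        overlap = par & (d < pop.radius + r_t)
        pop.remove(overlap)
        pop.add(center[None, :], TYPE_TUMOR, radius=r_t)
    else:
        diameters = list(spec.diameters)
        centers = spec.centers
        if centers is None:
            centers = default_disk_layout(cfg.domain, diameters)
        else:
            _validate_disks(cfg.domain, diameters, centers)
        spacing = 2.0 * r_t * 0.95
        for d, c in zip(diameters, centers):
            c = np.asarray(c, dtype=float)
            disk_r = 0.5 * d
            par = pop.is_parenchyma
            dist = np.linalg.norm(pop.position - c, axis=1)
            pop.remove(par & (dist < disk_r))
            cells = _hex_disk(c, max(disk_r - r_t, 0.0), spacing)
            if len(cells) == 0:
                cells = c[None, :]
            pop.add(cells, TYPE_TUMOR, radius=r_t, static=True)
    perfusion.mark_disrupted(state.field, pop.position[pop.is_tumor])
    _invalidate_pairs(state)
    return state


def initialize(config: ScenarioConfig) -> SimulationState:
    """Generate tissue, burn in the parenchyma packing, init field, seed."""
    tissue = generate_tissue(config)
    pop = CellPopulation(thickness=config.domain.thickness)
    if len(tissue.parenchyma):
        pop.add(
            tissue.parenchyma.positions,
            TYPE_PARENCHYMA,
            radius=tissue.parenchyma.radius,
            anchored=True,
        )
    state = SimulationState(
        config=config,
        tissue=tissue,
        pop=pop,
        field=None,
        mechanics_params=replace(config.mechanics),
        rng_sim=rng_stream(config.seed, "simulation"),
        rng_div=rng_stream(config.seed, "division"),
        rng_tie=rng_stream(config.seed, "tiebreak"),
    )
    mechanics.ensure_pressure_scale(state.mechanics_params)

    # mechanics-only burn-in relaxes the slightly compressed initial packing;
    # anchors are then reset so the equilibrium state carries no deformation
    n_burn = int(round(config.burn_in_min / config.dt_mech))
    for _ in range(n_burn):
        pairs = _current_pairs(state)
        moved = mechanics.motion_step(
            pop, pairs, state.mechanics_params, config.dt_mech, state.rng_tie
        )
        _note_motion(state, moved)
        if moved < 1e-3:  # um per step: packing has relaxed
            break
    par = pop.is_parenchyma
    pop.anchor[par] = pop.position[par]

    state.field = perfusion.init_field(tissue, config.transport, config.dx)
    seed_tumor(state, config.seeding, state.rng_sim)
    _update_pressures(state)
    _sample_oxygen(state)
    return state


# ---------------------------------------------------------------------------
# pair cache

def _invalidate_pairs(state: SimulationState) -> None:
    state._pairs = None
    state._pair_positions = None
    state._pair_radii = None


def _current_pairs(state: SimulationState) -> np.ndarray:
    pop = state.pop
    if state._pairs is not None and len(state._pair_positions) == len(pop):
        if len(pop):
            radii = pop.radius
            drift = float(
                np.abs(pop.position - state._pair_positions).max()
                + 2.5 * np.abs(radii - state._pair_radii).max()
            )
        else:
            drift = 0.0
        if drift <= 0.5 * _PAIR_SKIN:
            return state._pairs
    max_r = float(pop.radius.max()) if len(pop) else 1.0
    cutoff = mechanics.interaction_cutoff(state.mechanics_params, max_r) + _PAIR_SKIN
    state._pairs = mechanics.neighbor_pairs(pop.position, cutoff)
    state._pair_positions = pop.position.copy()
    state._pair_radii = pop.radius.copy()
    return state._pairs


def _note_motion(state: SimulationState, moved: float) -> None:
    # cheap guard: cache validity is re-checked against stored positions, so
    # nothing to do here beyond keeping the hook for profiling
    return


def _update_pressures(state: SimulationState) -> None:
    pop = state.pop
    if len(pop) == 0:
        return
    pairs = _current_pairs(state)
    pop.pressure = mechanics.compute_pressures(
        pop.position, pop.radius, state.mechanics_params, pairs
    )


def _sample_oxygen(state: SimulationState) -> None:
    if len(state.pop):
        state.pop.oxygen = state.field.sample(state.pop.position)


def _cell_sources(state: SimulationState) -> CellSources | None:
    pop = state.pop
    tp = state.config.transport
    live = pop.is_tumor & pop.is_viable
    if not live.any():
        return None
    n = int(live.sum())
    return CellSources(
        positions=pop.position[live],
        volumes=pop.volume[live],
        uptake=np.full(n, tp.U_cell),
        secretion=np.full(n, tp.S_cell),
        rho_star=np.full(n, tp.rho_star),
    )


# ---------------------------------------------------------------------------
# stepping

def _apply_events(state: SimulationState) -> None:
    for ev in state.config.events:
        if state.clock >= ev.time_min and not getattr(ev, "_applied", False):
            state.mechanics_params = replace(ev.mechanics)
            mechanics.ensure_pressure_scale(state.mechanics_params)
            object.__setattr__(ev, "_applied", True)


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one macro-step of ``dt_phen`` minutes."""
    cfg = state.config
    pop = state.pop
    _apply_events(state)

    # (1) permanent flow disruption under tumor cells
    perfusion.mark_disrupted(state.field, pop.position[pop.is_tumor])

    # (2) oxygen field
    n_sub = cfg.diffusion_substeps or max(1, int(round(cfg.dt_phen / cfg.dt_diff)))
    dt_sub = cfg.dt_phen / n_sub
    sources = _cell_sources(state)
    if not state.field.dirichlet_mask.all():
        for _ in range(n_sub):
            perfusion.step_diffusion(state.field, sources, dt_sub)

    # (3) mechanics
    movable = (~pop.static).any()
    if movable:
        n_mech = max(1, int(round(cfg.dt_phen / cfg.dt_mech)))
        for _ in range(n_mech):
            pairs = _current_pairs(state)
            mechanics.motion_step(
                pop, pairs, state.mechanics_params, cfg.dt_mech, state.rng_tie
            )

    # (4) pressures and oxygen seen by the cells
    _update_pressures(state)
    _sample_oxygen(state)

    # (5) phenotype
    dividing = phenotype.advance_phase(pop, cfg.dt_phen, cfg.phenotype, state.rng_sim)
    phenotype.necrosis_check(pop, cfg.dt_phen, cfg.phenotype, state.rng_sim)
    phenotype.update_volume(pop, cfg.dt_phen, cfg.phenotype)
    if len(dividing):
        phenotype.divide(pop, dividing, state.rng_div)
        _invalidate_pairs(state)

    par_strain = (
        pop.is_parenchyma
        & pop.is_viable
        & mechanics.strain_death_check(pop.deformation, state.mechanics_params)
    )
    if par_strain.any():
        phenotype.trigger_apoptosis(pop, np.where(par_strain)[0])
        pop.parenchyma_apoptosis_count += int(par_strain.sum())
    if phenotype.remove_dead(pop):
        _invalidate_pairs(state)

    state.clock += cfg.dt_phen
    return state


def run_simulation(
    config: ScenarioConfig,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> SimulationState:
    """Run a scenario to its configured duration, collecting metrics.

    Metrics are appended every ``snapshot_interval`` minutes (and at t=0);
    when ``out_dir`` is given, SVG snapshots, the metrics table, and the
    final cell table are written there.
    """
    from hepamet import outputs

    state = initialize(config)
    total_min = config.duration_days * 24.0 * 60.0
    n_steps = int(round(total_min / config.dt_phen))
    every = max(1, int(round(config.snapshot_interval / config.dt_phen)))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    state.metrics.append(outputs.compute_metrics(state))
    for k in range(1, n_steps + 1):
        step(state)
        if k % every == 0:
            state.metrics.append(outputs.compute_metrics(state))
            if out is not None:
                svg = outputs.render_svg(state)
                (out / f"snapshot_t{int(state.clock):08d}min.svg").write_text(svg)
    if out is not None:
        state.metrics_frame().to_csv(out / "metrics.csv", index=False)
        outputs.write_cell_table(state, out / "cells_final.csv")
    return state


# ---------------------------------------------------------------------------
# checkpointing

def checkpoint_bytes(state: SimulationState) -> bytes:
    payload = {
        "format": CHECKPOINT_FORMAT,
        "version": CHECKPOINT_VERSION,
        "state": state,
    }
    return pickle.dumps(payload, protocol=pickle.HIGHEST_PROTOCOL)


def checkpoint(state: SimulationState, path: str | Path) -> None:
    """Write a self-describing checkpoint container."""
    Path(path).write_bytes(checkpoint_bytes(state))


def restore_bytes(
    blob: bytes, mechanics_params: MechanicsParams | None = None
) -> SimulationState:
    try:
        payload = pickle.loads(blob)
        fmt = payload["format"]
        version = payload["version"]
        state = payload["state"]
    except Exception as exc:  # corrupt container: no partial state escapes
        raise ValueError(f"unreadable checkpoint: {exc}") from exc
    if fmt != CHECKPOINT_FORMAT or version != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint format/version mismatch: got {fmt!r} v{version!r}"
        )
    if mechanics_params is not None:
        state.mechanics_params = replace(mechanics_params)
        mechanics.ensure_pressure_scale(state.mechanics_params)
    return state


def restore(
    path: str | Path, mechanics_params: MechanicsParams | None = None
) -> SimulationState:
    """Load a checkpoint; optionally swap in new biomechanical parameters."""
    return restore_bytes(Path(path).read_bytes(), mechanics_params)


# ---------------------------------------------------------------------------
# protocols

def _derived_seed(base_seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_growth_sweep(
    base_config: ScenarioConfig,
    triplets: list[tuple[float, float, float]] | None = None,
    replicates: int = 10,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the biomechanics sweep: one run per (r_E, r_P, d_max, replicate).

    ``triplets`` defaults to the full 3 x 3 x 3 grid. Each run gets a
    distinct derived seed. Failed runs are recorded and the sweep continues.
    Returns a summary frame with the final tumor area per run.
    """
    from hepamet.params import SWEEP_GRID

    if triplets is None:
        triplets = list(
            itertools.product(SWEEP_GRID["r_E"], SWEEP_GRID["r_P"], SWEEP_GRID["d_max"])
        )
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    for t_idx, (r_e, r_p, d_max) in enumerate(triplets):
        for rep in range(replicates):
            seed = _derived_seed(base_config.seed, t_idx, rep)
            cfg = replace(
                base_config,
                mechanics=replace(base_config.mechanics, r_E=r_e, r_P=r_p, d_max=d_max, p_scale=None),
                seed=seed,
            )
            run_out = out / f"run_t{t_idx}_r{rep}" if out is not None else None
            row = {
                "r_E": r_e,
                "r_P": r_p,
                "d_max": d_max,
                "replicate": rep,
                "seed": seed,
            }
            try:
                st = run_simulation(cfg, out_dir=run_out)
                last = st.metrics[-1]
                row.update(
                    final_tumor_area=last["tumor_area"],
                    final_tumor_diameter=last["tumor_diameter"],
                    final_viable_tumor_cells=last["n_ki67_neg"]
                    + last["n_ki67_pre"]
                    + last["n_ki67_post"],
                    error="",
                )
            except Exception as exc:  # record and continue
                warnings.warn(f"sweep run failed: {exc}", stacklevel=2)
                row.update(
                    final_tumor_area=np.nan,
                    final_tumor_diameter=np.nan,
                    final_viable_tumor_cells=np.nan,
                    error=str(exc),
                )
            rows.append(row)
    summary = pd.DataFrame(rows)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "sweep_summary.csv", index=False)
    return summary


def run_reawakening(
    config: ScenarioConfig,
    stage2_days: float | None = None,
) -> dict[str, dict]:
    """Dormancy/reawakening protocol with three stage-2 branches.

    Stage 1 grows a tumor to dormancy under the configured (stiff, tolerant)
    triplet, checkpoints, then three branches resume from the byte-identical
    checkpoint: I leaves parameters unchanged; II drops r_E to 0.05/min
    (increased deformability); III drops d_max to 1.5 um (reduced tolerance
    to deformation).
    """
    from hepamet import outputs

    stage2 = stage2_days if stage2_days is not None else config.duration_days
    stage1 = run_simulation(config)
    blob = checkpoint_bytes(stage1)
    ckpt_area = stage1.metrics[-1]["tumor_area"]

    base = stage1.mechanics_params
    branch_params = {
        "I": replace(base),
        "II": replace(base, r_E=0.05, p_scale=None),
        "III": replace(base, d_max=1.5, p_scale=None),
    }
    results: dict[str, dict] = {}
    n_steps = int(round(stage2 * 24.0 * 60.0 / config.dt_phen))
    every = max(1, int(round(config.snapshot_interval / config.dt_phen)))
    for name, mech in branch_params.items():
        st = restore_bytes(blob, mechanics_params=mech)
        for k in range(1, n_steps + 1):
            step(st)
            if k % every == 0:
                st.metrics.append(outputs.compute_metrics(st))
        final_area = st.metrics[-1]["tumor_area"]
        results[name] = {
            "state": st,
            "metrics": st.metrics_frame(),
            "checkpoint_area": ckpt_area,
            "final_area": final_area,
            "relative_growth": (final_area - ckpt_area) / max(ckpt_area, 1e-12),
        }
    return results


def run_oxygen_study(
    config: ScenarioConfig,
    tol: float = 1e-5,
    dt: float | None = None,
) -> tuple[SimulationState, pd.DataFrame]:
    """Static-tumor steady-state oxygenation study.

    Seeds the configured static disks, solves the oxygen field to steady
    state, and returns the state plus the per-tumor oxygen-versus-depth
    table.
    """
    from hepamet import outputs

    if config.seeding.mode != "disks":
        raise ConfigurationError("oxygen study requires disk seeding")
    # mechanics is disabled throughout the static study, so the packing
    # burn-in would only cost time without affecting the field
    config = replace(config, burn_in_min=0.0)
    state = initialize(config)
    perfusion.solve_steady(
        state.field,
        _cell_sources(state),
        tol=tol,
        dt=dt if dt is not None else config.dt_diff,
    )
    _sample_oxygen(state)
    curves = outputs.oxygen_vs_depth(state.field, state.pop)
    return state, curves
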