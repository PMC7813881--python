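"""Oxygen field: quasi-steady perfused tissue plus diffusion in tumors.

Intact parenchyma is well perfused and advection-dominated, so its oxygen is
quasi-steady: every voxel of intact tissue is a Dirichlet node pinned to an
analytic single-lobule profile that rises from ``sigma_cv`` (~38 mmHg) at the
central vein to ``sigma_pt`` (~60 mmHg) at the lobule boundary (the
portal-triad proxy). Flow is stagnant inside micrometastases, so any voxel
that ever contains a tumor cell is *permanently disrupted*: its Dirichlet
node is removed forever and its oxygen evolves by finite-volume
reaction-diffusion

    d rho/dt = D lap(rho) - lambda rho
               + sum_i delta(x - x_i) W_i [S_i (rho*_i - rho) - U_i rho]

with zero-flux outer boundaries. The solver uses first-order operator
splitting per dimension with implicit (tridiagonal) sweeps; cell sources and
sinks are folded in by a backward-Euler voxel update, so the scheme is
unconditionally stable. Dirichlet voxels are carried as identity rows in the
tridiagonal systems, which keeps them exact and decouples intact regions
from the solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from hepamet.params import ConfigurationError, TransportParams
from hepamet.tissue_gen import LobuleMap, Tissue

_EXP_PROFILE_RATE = 3.0  # shape constant of the exponential-saturation profile


@dataclass
class CellSources:
    """Off-lattice cell source/sink terms for the substrate solver."""

    positions: np.ndarray   # (n, 2) um
    volumes: np.ndarray     # (n,) um^3
    uptake: np.ndarray      # (n,) 1/min
    secretion: np.ndarray   # (n,) 1/min
    rho_star: np.ndarray    # (n,) mmHg

    @classmethod
    def uniform(
        cls,
        positions: np.ndarray,
        volume: float,
        uptake: float,
        secretion: float = 0.0,
        rho_star: float = 38.0,
    ) -> "CellSources":
        n = len(positions)
        return cls(
            positions=np.asarray(positions, dtype=float).reshape(-1, 2),
            volumes=np.full(n, float(volume)),
            uptake=np.full(n, float(uptake)),
            secretion=np.full(n, float(secretion)),
            rho_star=np.full(n, float(rho_star)),
        )


@dataclass
class SubstrateField:
    """Gridded oxygen field with per-voxel Dirichlet and disruption flags.

    Arrays are indexed ``[iy, ix]``; voxel centers sit at ``(i + 0.5) dx``.
    """

    dx: float
    nx: int
    ny: int
    thickness: float
    values: np.ndarray           # (ny, nx) mmHg
    dirichlet_mask: np.ndarray   # (ny, nx) bool
    dirichlet_values: np.ndarray  # (ny, nx) mmHg
    disrupted_mask: np.ndarray   # (ny, nx) bool, permanent
    params: TransportParams = field(default_factory=TransportParams)

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dx * self.thickness

    def voxel_indices(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(iy, ix) of the voxels containing the given points (clipped)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ix = np.clip((pts[:, 0] // self.dx).astype(int), 0, self.nx - 1)
        iy = np.clip((pts[:, 1] // self.dx).astype(int), 0, self.ny - 1)
        return iy, ix

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel oxygen at the given points."""
        iy, ix = self.voxel_indices(points)
        return self.values[iy, ix]

    def copy(self) -> "SubstrateField":
        return SubstrateField(
            dx=self.dx,
            nx=self.nx,
            ny=self.ny,
            thickness=self.thickness,
            values=self.values.copy(),
            dirichlet_mask=self.dirichlet_mask.copy(),
            dirichlet_values=self.dirichlet_values.copy(),
            disrupted_mask=self.disrupted_mask.copy(),
            params=self.params,
        )


# ---------------------------------------------------------------------------
# analytic perfusion profile

def _profile_shape(u: np.ndarray, profile: str) -> np.ndarray:
    if profile == "linear":
        return u
    # exponential saturation, normalized to g(0)=0, g(1)=1
    k = _EXP_PROFILE_RATE
    return (1.0 - np.exp(-k * u)) / (1.0 - np.exp(-k))


def analytic_oxygen(
    points: np.ndarray, lobules: LobuleMap | None, params: TransportParams
) -> np.ndarray:
    """Quasi-steady oxygen at points of intact tissue.

    The normalized along-flow coordinate ``u`` of a point is its distance to
    the lobule's central vein divided by the distance from the vein through
    the point to the lobule (Voronoi region) boundary, so ``u = 0`` at the
    vein and ``u = 1`` at the portal proxy. The returned value is
    ``sigma_cv + (sigma_pt - sigma_cv) g(u)``. Points outside all regions
    fall back to their nearest region; a tissue without central veins is
    uniformly at ``sigma_pt``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if lobules is None or len(lobules.cv_points) == 0:
        return np.full(len(pts), params.sigma_pt)

    idx = lobules.region_index(pts)
    u = np.zeros(len(pts))
    for region in np.unique(idx):
        sel = np.where(idx == region)[0]
        cv = lobules.cv_points[region]
        poly = lobules.polygons[region]
        rel = pts[sel] - cv
        r = np.hypot(rel[:, 0], rel[:, 1])
        at_cv = r < 1e-12
        d = np.where(r[:, None] > 0, rel / np.maximum(r, 1e-300)[:, None], 0.0)
        t_b = _ray_boundary_distance(cv, d, poly)
        with np.errstate(invalid="ignore", divide="ignore"):
            uu = np.where(at_cv | (t_b <= 0), 0.0, r / np.maximum(t_b, 1e-300))
        u[sel] = np.clip(uu, 0.0, 1.0)

    g = _profile_shape(u, params.profile)
    return params.sigma_cv + (params.sigma_pt - params.sigma_cv) * g


def _ray_boundary_distance(
    origin: np.ndarray, directions: np.ndarray, polygon: np.ndarray
) -> np.ndarray:
    """Distance from ``origin`` along each unit direction to the polygon rim.

    Vectorized ray/segment intersection over all polygon edges; the smallest
    positive hit is returned (inf if a degenerate direction misses).
    """
    v1 = polygon
    v2 = np.roll(polygon, -1, axis=0)
    e = v2 - v1                      # (m, 2)
    w = v1 - origin                  # (m, 2)
    # cross products for each (direction, edge) pair
    denom = directions[:, None, 0] * e[None, :, 1] - directions[:, None, 1] * e[None, :, 0]
    num_t = w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]
    num_s = w[None, :, 0] * directions[:, None, 1] - w[None, :, 1] * directions[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num_t / denom
        s = num_s / denom
    ok = (np.abs(denom) > 1e-14) & (t > 1e-12) & (s >= -1e-9) & (s <= 1 + 1e-9)
    t = np.where(ok, t, np.inf)
    return t.min(axis=1)


def init_field(
    tissue: Tissue, params: TransportParams, dx: float = 20.0
) -> SubstrateField:
    """All-Dirichlet field pinned to the analytic profile at voxel centers."""
    if dx <= 0:
        raise ConfigurationError("voxel edge must be positive")
    nx = max(1, int(round(tissue.domain.width / dx)))
    ny = max(1, int(round(tissue.domain.height / dx)))
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dx
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    vals = analytic_oxygen(centers, tissue.lobules, params).reshape(ny, nx)
    return SubstrateField(
        dx=dx,
        nx=nx,
        ny=ny,
        thickness=tissue.domain.thickness,
        values=vals,
        dirichlet_mask=np.ones((ny, nx), dtype=bool),
        dirichlet_values=vals.copy(),
        disrupted_mask=np.zeros((ny, nx), dtype=bool),
        params=params,
    )


def mark_disrupted(field: SubstrateField, tumor_positions: np.ndarray) -> SubstrateField:
    """Permanently remove Dirichlet nodes from tumor-occupied voxels.

    A voxel counts as occupied when a tumor cell *center* lies inside it.
    Disruption is irreversible: the flag persists if the cell later dies or
    moves away. The field is modified in place and returned.
    """
    pts = np.asarray(tumor_positions, dtype=float).reshape(-1, 2)
    if len(pts):
        iy, ix = field.voxel_indices(pts)
        field.disrupted_mask[iy, ix] = True
        field.dirichlet_mask[iy, ix] = False
    return field


# ---------------------------------------------------------------------------
# finite-volume solver

def _voxelize_sources(
    field: SubstrateField, cells: CellSources | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel total source rate S (1/min) and S-weighted target, plus uptake.

    Returns ``(S_tot, S_rho_star, U_tot)`` folded as (S_tot, S_rho*, U_tot);
    cell rates are scaled by cell volume over voxel volume (the discrete
    delta-kernel of the conservation law).
    """
    shape = (field.ny, field.nx)
    S_tot = np.zeros(shape)
    S_rho = np.zeros(shape)
    U_tot = np.zeros(shape)
    if cells is not None and len(cells.positions):
        iy, ix = field.voxel_indices(cells.positions)
        w = cells.volumes / field.voxel_volume
        np.add.at(S_tot, (iy, ix), cells.secretion * w)
        np.add.at(S_rho, (iy, ix), cells.secretion * w * cells.rho_star)
        np.add.at(U_tot, (iy, ix), cells.uptake * w)
    return S_tot, S_rho, U_tot


def _tridiagonal_sweep(
    values: np.ndarray,
    dirichlet_mask: np.ndarray,
    dirichlet_values: np.ndarray,
    k: float,
    half_decay: float,
    dt: float,
) -> np.ndarray:
    """One implicit sweep along axis 1 (rows solved independently).

    ``k = D dt / dx^2``. Dirichlet voxels are identity rows pinned to their
    prescribed values, which both enforces them exactly and decouples the
    intact-tissue background; rows with no unknowns are skipped.
    """
    ny, nx = values.shape
    free = ~dirichlet_mask
    rows = np.where(free.any(axis=1))[0]
    if len(rows) == 0:
        return values
    cols = np.where(free.any(axis=0))[0]
    lo = max(0, cols[0] - 1)
    hi = min(nx, cols[-1] + 2)
    n = hi - lo

    vals = values[rows][:, lo:hi]
    mask = dirichlet_mask[rows][:, lo:hi]
    pin = dirichlet_values[rows][:, lo:hi]

    # neighbor counts along the sweep axis (zero-flux at true domain edges)
    nb = np.full(n, 2.0)
    if lo == 0:
        nb[0] = 1.0
    if hi == nx:
        nb[-1] = 1.0

    a = np.where(mask, 0.0, -k)
    c = np.where(mask, 0.0, -k)
    b = np.where(mask, 1.0, 1.0 + dt * half_decay + k * nb[None, :])
    d = np.where(mask, pin, vals)
    a[:, 0] = 0.0
    c[:, -1] = 0.0
    # crop-edge voxels not on the domain edge are Dirichlet by construction,
    # so no flux is lost at the crop boundary

    # Thomas algorithm, vectorized across rows
    cp = np.empty_like(c)
    dp = np.empty_like(d)
    cp[:, 0] = c[:, 0] / b[:, 0]
    dp[:, 0] = d[:, 0] / b[:, 0]
    for i in range(1, n):
        m = b[:, i] - a[:, i] * cp[:, i - 1]
        cp[:, i] = c[:, i] / m
        dp[:, i] = (d[:, i] - a[:, i] * dp[:, i - 1]) / m
    x = np.empty_like(d)
    x[:, -1] = dp[:, -1]
    for i in range(n - 2, -1, -1):
        x[:, i] = dp[:, i] - cp[:, i] * x[:, i + 1]

    out = values.copy()
    out[np.ix_(rows, np.arange(lo, hi))] = x
    return out


def step_diffusion(
    field: SubstrateField, cells: CellSources | None, dt: float = 0.01
) -> SubstrateField:
    """Advance the reaction-diffusion problem by one step of ``dt`` minutes.

    Order per step: backward-Euler cell sources/sinks per voxel, then
    implicit x and y diffusion sweeps each carrying half the bulk decay,
    then re-pinning of Dirichlet voxels. First order in time, second order
    in space. The field is updated in place and returned.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    p = field.params
    S_tot, S_rho, U_tot = _voxelize_sources(field, cells)

    vals = field.values
    # cell kinetics, backward Euler (coupled to the new voxel value)
    denom = 1.0 + dt * (S_tot + U_tot)
    vals = (vals + dt * S_rho) / denom

    k = p.D * dt / field.dx**2
    half = 0.5 * p.decay
    if k > 0:
        vals = _tridiagonal_sweep(
            vals, field.dirichlet_mask, field.dirichlet_values, k, half, dt
        )
        vals = _tridiagonal_sweep(
            vals.T,
            field.dirichlet_mask.T,
            field.dirichlet_values.T,
            k,
            half,
            dt,
        ).T
    else:
        vals = vals / (1.0 + dt * p.decay)

    vals = np.where(field.dirichlet_mask, field.dirichlet_values, vals)
    if (vals < -1e-9).any():
        raise RuntimeError(
            "diffusion produced negative concentrations "
            f"(min {vals.min():.3e} mmHg); check the step size and rates"
        )
    field.values = np.maximum(vals, 0.0)
    return field


def solve_steady(
    field: SubstrateField,
    cells: CellSources | None,
    tol: float = 1e-5,
    dt: float = 0.01,
    max_steps: int = 10**6,
) -> SubstrateField:
    """Iterate :func:`step_diffusion` to steady state.

    Convergence when the maximum relative change per minute drops below
    ``tol``; warns (and returns the best iterate) if ``max_steps`` is hit.
    """
    if tol <= 0:
        raise ConfigurationError("tolerance must be positive")
    if field.dirichlet_mask.all():
        # fully quasi-steady field: one enforcement step suffices
        field.values = field.dirichlet_values.copy()
        return field
    scale = max(float(np.abs(field.values).max()), 1e-12)
    for _ in range(max_steps):
        prev = field.values.copy()
        step_diffusion(field, cells, dt)
        resid = float(np.abs(field.values - prev).max()) / (dt * scale)
        if resid < tol:
            return field
    warnings.warn(
        f"steady-state cap reached (residual {resid:.3e}/min > {tol:g}/min)",
        stacklevel=2,
    )
    return field


def field_table(field: SubstrateField) -> "pd.DataFrame":  # noqa: F821
    """Gridded field snapshot as a tidy table (x, y, pO2, dirichlet, disrupted)."""
    import pandas as pd

    xs = (np.arange(field.nx) + 0.5) * field.dx
    ys = (np.arange(field.ny) + 0.5) * field.dx
    gx, gy = np.meshgrid(xs, ys)
    return pd.DataFrame(
        {
            "x": gx.ravel(),
            "y": gy.ravel(),
            "pO2": field.values.ravel(),
            "dirichlet": field.dirichlet_mask.ravel(),
            "disrupted": field.disrupted_mask.ravel(),
        }
    )
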