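"""Synthetic 2-D virtual liver tissue.

Hepatic lobules are approximated by the Voronoi tessellation of randomly
placed central veins (CVs): CVs are dropped uniformly at a mean density of
~2e-6 per um^2 (giving a mean lobule equivalent diameter near 800 um),
closely spaced pairs are merged at their midpoints, and the remaining space
is filled with hexagonally packed parenchyma agents. Voronoi vertices serve
as portal-triad proxy points for the perfusion profile.

The Voronoi diagram is clipped to the rectangular domain exactly by
tessellating the CV points together with their mirror images across the four
domain edges; each original point's region is then finite and coincides with
the clipped region of the unbounded diagram.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import QhullError, Voronoi, cKDTree

from hepamet.params import ConfigurationError, Domain, ScenarioConfig, TissueParams
from hepamet.rng import rng_stream

_EDGE_TOL = 1e-6  # um; vertices closer than this to an edge count as clipped


@dataclass
class CentralVeinSet:
    """Central-vein positions (um) in a domain."""

    points: np.ndarray  # (n, 2)
    density: float      # requested mean density, per um^2

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class LobuleMap:
    """Bounded Voronoi tessellation of the domain by central veins.

    ``polygons[i]`` is the (counter-clockwise) vertex array of the region of
    ``cv_points[i]`` clipped to the domain. ``interior[i]`` is False for
    regions truncated by the domain boundary; tissue summary statistics use
    interior regions only. ``vertices`` are the distinct region vertices not
    on the domain boundary, used as portal-triad proxy points.
    """

    cv_points: np.ndarray
    domain: Domain
    polygons: list = field(default_factory=list)
    interior: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    vertices: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def region_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest-CV region index for query points (vectorized)."""
        if len(self.cv_points) == 0:
            raise ConfigurationError("lobule map has no central veins")
        if self._tree is None:
            self._tree = cKDTree(self.cv_points)
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self._tree.query(pts)[1]

    def areas(self) -> np.ndarray:
        """Region areas (um^2) by the shoelace formula."""
        return np.array([_polygon_area(p) for p in self.polygons])

    def equivalent_diameters(self) -> np.ndarray:
        """2 sqrt(area / pi) per region."""
        return 2.0 * np.sqrt(self.areas() / np.pi)


@dataclass
class ParenchymaLayout:
    """Hexagonally packed parenchyma agent centers."""

    positions: np.ndarray  # (n, 2)
    radius: float
    spacing: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class Tissue:
    """Composite synthetic tissue: veins, lobule geometry, parenchyma."""

    domain: Domain
    cvs: CentralVeinSet
    lobules: LobuleMap | None
    parenchyma: ParenchymaLayout
    params: TissueParams
    seed: int


# ---------------------------------------------------------------------------
# operations

def place_central_veins(
    domain: Domain, density: float, rng_seed: int | np.random.Generator
) -> CentralVeinSet:
    """Drop central veins uniformly at the given mean density.

    The count is Poisson with mean ``density * area``; positions are uniform
    over the domain. Deterministic for a fixed seed.
    """
    if density < 0:
        raise ConfigurationError("CV density must be nonnegative")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = rng.poisson(density * domain.area)
    pts = rng.uniform((0.0, 0.0), (domain.width, domain.height), size=(n, 2))
    return CentralVeinSet(points=pts, density=density)


def merge_close_pairs(cvs: CentralVeinSet, min_separation: float) -> CentralVeinSet:
    """Merge closely spaced CV pairs at their midpoints.

    The closest pair is merged first; merging repeats until no two points
    are closer than ``min_separation``.
    """
    if min_separation <= 0:
        raise ConfigurationError("min_separation must be positive")
    pts = [p for p in np.asarray(cvs.points, dtype=float)]
    while len(pts) >= 2:
        arr = np.asarray(pts)
        diff = arr[:, None, :] - arr[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] >= min_separation:
            break
        mid = 0.5 * (arr[i] + arr[j])
        pts = [p for k, p in enumerate(pts) if k not in (i, j)]
        pts.append(mid)
    out = np.asarray(pts).reshape(-1, 2)
    return CentralVeinSet(points=out, density=cvs.density)


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _mirror_points(pts: np.ndarray, domain: Domain) -> np.ndarray:
    left = pts * [-1, 1]
    right = pts * [-1, 1] + [2 * domain.width, 0]
    down = pts * [1, -1]
    up = pts * [1, -1] + [0, 2 * domain.height]
    return np.vstack([pts, left, right, down, up])


def build_lobule_map(cvs: CentralVeinSet, domain: Domain) -> LobuleMap:
    """Clipped Voronoi tessellation of the domain by the CV points."""
    pts = np.asarray(cvs.points, dtype=float)
    if len(pts) == 0:
        raise ConfigurationError("need at least one central vein")
    if len(pts) == 1:
        poly = np.array(
            [[0, 0], [domain.width, 0], [domain.width, domain.height], [0, domain.height]],
            dtype=float,
        )
        return LobuleMap(
            cv_points=pts,
            domain=domain,
            polygons=[poly],
            interior=np.array([False]),
            vertices=np.zeros((0, 2)),
        )

    mirrored = _mirror_points(pts, domain)
    try:
        vor = Voronoi(mirrored)
    except QhullError:
        vor = Voronoi(mirrored, qhull_options="Qbb Qc Qz QJ")

    polygons: list[np.ndarray] = []
    interior = np.zeros(len(pts), dtype=bool)
    interior_vertices: list[np.ndarray] = []
    w, h = domain.width, domain.height
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # clamp round-off excursions outside the rectangle
        verts = np.clip(verts, [0.0, 0.0], [w, h])
        polygons.append(verts)
        on_edge = (
            (verts[:, 0] < _EDGE_TOL)
            | (verts[:, 0] > w - _EDGE_TOL)
            | (verts[:, 1] < _EDGE_TOL)
            | (verts[:, 1] > h - _EDGE_TOL)
        )
        interior[i] = not on_edge.any()
        if (~on_edge).any():
            interior_vertices.append(verts[~on_edge])

    if interior_vertices:
        allv = np.vstack(interior_vertices)
        vertices = np.unique(np.round(allv, 6), axis=0)
    else:
        vertices = np.zeros((0, 2))
    return LobuleMap(
        cv_points=pts,
        domain=domain,
        polygons=polygons,
        interior=interior,
        vertices=vertices,
    )


def pack_parenchyma(
    domain: Domain,
    lobules: LobuleMap | None,
    radius: float,
    spacing: float,
    cv_exclusion_radius: float,
) -> ParenchymaLayout:
    """Fill the domain with a triangular (hex-packed) lattice of agents.

    Rows are offset by ``spacing * sqrt(3)/2``; odd rows shift by half a
    spacing. Lattice points within ``cv_exclusion_radius`` of any central
    vein are omitted. Deterministic for fixed inputs.
    """
    if spacing <= 0 or radius <= 0:
        raise ConfigurationError("spacing and radius must be positive")
    if spacing < radius:
        warnings.warn(
            "parenchyma spacing below agent radius: heavy initial overlap",
            stacklevel=2,
        )
    dy = spacing * np.sqrt(3.0) / 2.0
    tol = 1e-9 * max(domain.width, domain.height, 1.0)
    ys = np.arange(0.0, domain.height + tol, dy)
    rows = []
    for j, y in enumerate(ys):
        x0 = 0.5 * spacing if j % 2 else 0.0
        xs = np.arange(x0, domain.width + tol, spacing)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
    pts = np.vstack(rows) if rows else np.zeros((0, 2))

    if lobules is not None and len(lobules.cv_points) > 0 and len(pts) > 0:
        tree = cKDTree(lobules.cv_points)
        d, _ = tree.query(pts)
        pts = pts[d >= cv_exclusion_radius]
    return ParenchymaLayout(positions=pts, radius=radius, spacing=spacing)


def generate_tissue(config: ScenarioConfig) -> Tissue:
    """Place veins, merge pairs, tessellate, and pack the parenchyma."""
    tp = config.tissue
    rng = rng_stream(config.seed, "tissue")
    cvs = place_central_veins(config.domain, tp.cv_density, rng)
    cvs = merge_close_pairs(cvs, tp.min_separation)
    lobules = build_lobule_map(cvs, config.domain) if len(cvs) else None
    layout = pack_parenchyma(
        config.domain, lobules, tp.parenchyma_radius, tp.spacing, tp.cv_exclusion_radius
    )
    return Tissue(
        domain=config.domain,
        cvs=cvs,
        lobules=lobules,
        parenchyma=layout,
        params=tp,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# persistence: CSV agent table + JSON sidecar

def write_tissue(tissue: Tissue, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = len(tissue.parenchyma)
    df = pd.DataFrame(
        {
            "agent_id": np.arange(n),
            "type": "parenchyma",
            "x": tissue.parenchyma.positions[:, 0],
            "y": tissue.parenchyma.positions[:, 1],
            "radius": tissue.parenchyma.radius,
        }
    )
    df.to_csv(out / "tissue_agents.csv", index=False)
    sidecar = {
        "domain": {
            "width": tissue.domain.width,
            "height": tissue.domain.height,
            "thickness": tissue.domain.thickness,
        },
        "cv_points": tissue.cvs.points.tolist(),
        "cv_density": tissue.cvs.density,
        "seed": tissue.seed,
        "params": {
            "cv_density": tissue.params.cv_density,
            "min_separation": tissue.params.min_separation,
            "parenchyma_radius": tissue.params.parenchyma_radius,
            "spacing_factor": tissue.params.spacing_factor,
            "cv_exclusion_radius": tissue.params.cv_exclusion_radius,
        },
    }
    (out / "tissue_meta.json").write_text(json.dumps(sidecar, indent=1))


def read_tissue(in_dir: str | Path) -> Tissue:
    src = Path(in_dir)
    meta = json.loads((src / "tissue_meta.json").read_text())
    df = pd.read_csv(src / "tissue_agents.csv")
    domain = Domain(**meta["domain"])
    params = TissueParams(**meta["params"])
    cvs = CentralVeinSet(
        points=np.asarray(meta["cv_points"], dtype=float).reshape(-1, 2),
        density=meta["cv_density"],
    )
    lobules = build_lobule_map(cvs, domain) if len(cvs) else None
    layout = ParenchymaLayout(
        positions=df[["x", "y"]].to_numpy(dtype=float),
        radius=params.parenchyma_radius,
        spacing=params.spacing,
    )
    return Tissue(
        domain=domain,
        cvs=cvs,
        lobules=lobules,
        parenchyma=layout,
        params=params,
        seed=meta["seed"],
    )
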