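"""Metrics, tabular export, and SVG rendering of simulation states.

The SVG convention follows the study's figures: tumor cells are blue
(Ki67-), green (Ki67+ premitotic), magenta (Ki67+ postmitotic), red
(apoptotic) or brown (necrotic); viable tumor cells whose pressure exceeds
the arrest threshold are overridden to yellow. Parenchyma agents are shaded
on a continuous orange-to-gray ramp by relative deformation d_i/d_max, get
a black outline once displaced by at least 1% of d_max, and turn black when
apoptotic.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from hepamet.population import (
    PHASE_APOPTOTIC,
    PHASE_KI67_NEG,
    PHASE_KI67_POST,
    PHASE_KI67_PRE,
    PHASE_NECROTIC,
    PHASE_NAMES,
    TYPE_PARENCHYMA,
    TYPE_TUMOR,
)

TUMOR_COLORS = {
    PHASE_KI67_NEG: "#1f4fd8",   # blue, quiescent
    PHASE_KI67_PRE: "#2ca02c",   # green, premitotic
    PHASE_KI67_POST: "#d82ad8",  # magenta, postmitotic
    PHASE_APOPTOTIC: "#d62728",  # red
    PHASE_NECROTIC: "#8b4513",   # brown
}
PRESSURE_OVERRIDE_COLOR = "#ffd700"  # yellow: viable tumor with p > p2
PARENCHYMA_RAMP = ("#ff8c00", "#d3d3d3")  # orange (no strain) -> light gray
PARENCHYMA_DEAD_COLOR = "#000000"
OUTLINE_FRACTION = 0.01  # outline once d_i exceeds this fraction of d_max


# ---------------------------------------------------------------------------
# metrics

def tumor_area(state) -> float:
    """Area (um^2) of voxels holding >= 1 viable-or-necrotic tumor cell."""
    pop, fld = state.pop, state.field
    mask = pop.is_tumor & (pop.phase != PHASE_APOPTOTIC)
    if not mask.any():
        return 0.0
    occ = np.zeros((fld.ny, fld.nx), dtype=bool)
    iy, ix = fld.voxel_indices(pop.position[mask])
    occ[iy, ix] = True
    return float(occ.sum()) * fld.dx**2


def compute_metrics(state) -> dict:
    """One metrics row: phase counts, arrest fraction, displacement, size.

    The arrest fraction is computed over viable (non-apoptotic,
    non-necrotic) tumor cells; with zero viable tumor cells it is reported
    as 0 with ``no_viable_tumor`` flagged. Mean displacement runs over all
    live parenchyma agents. Pure function of the state except for the
    explicitly cumulative parenchyma apoptosis counter.
    """
    pop = state.pop
    p2 = state.config.phenotype.p2
    tumor = pop.is_tumor
    viable_tumor = tumor & pop.is_viable
    n_viable = int(viable_tumor.sum())
    if n_viable:
        frac = float((pop.pressure[viable_tumor] > p2).sum()) / n_viable
        mean_p = float(pop.pressure[viable_tumor].mean())
    else:
        frac, mean_p = 0.0, 0.0
    par_live = pop.is_parenchyma & pop.is_viable
    mean_disp = float(pop.deformation[par_live].mean()) if par_live.any() else 0.0
    area = tumor_area(state)
    return {
        "time_min": state.clock,
        "n_ki67_neg": int((tumor & (pop.phase == PHASE_KI67_NEG)).sum()),
        "n_ki67_pre": int((tumor & (pop.phase == PHASE_KI67_PRE)).sum()),
        "n_ki67_post": int((tumor & (pop.phase == PHASE_KI67_POST)).sum()),
        "n_apoptotic_tumor": int((tumor & (pop.phase == PHASE_APOPTOTIC)).sum()),
        "n_necrotic_tumor": int((tumor & (pop.phase == PHASE_NECROTIC)).sum()),
        "fraction_above_p2": frac,
        "no_viable_tumor": n_viable == 0,
        "mean_tumor_pressure": mean_p,
        "mean_parenchyma_displacement": mean_disp,
        "parenchyma_apoptosis_cum": state.pop.parenchyma_apoptosis_count,
        "tumor_area": area,
        "tumor_diameter": 2.0 * np.sqrt(area / np.pi),
    }


# ---------------------------------------------------------------------------
# SVG rendering

def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))


def _ramp(frac: np.ndarray, lo: str, hi: str) -> list[str]:
    a = np.array(_hex_to_rgb(lo), dtype=float)
    b = np.array(_hex_to_rgb(hi), dtype=float)
    f = np.clip(np.asarray(frac, dtype=float), 0.0, 1.0)[:, None]
    rgb = np.round(a + f * (b - a)).astype(int)
    return [f"#{r:02x}{g:02x}{b_:02x}" for r, g, b_ in rgb]


def render_svg(state, ramp: tuple[str, str] = PARENCHYMA_RAMP) -> str:
    """Render the state as an SVG document string (one circle per agent)."""
    pop = state.pop
    dom = state.config.domain
    p2 = state.config.phenotype.p2
    d_max = state.mechanics_params.d_max

    svg = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=f"{dom.width + 220:.0f}",
        height=f"{dom.height + 40:.0f}",
        viewBox=f"0 0 {dom.width + 220:.0f} {dom.height + 40:.0f}",
    )
    ET.SubElement(
        svg, "rect", x="0", y="0",
        width=f"{dom.width:.0f}", height=f"{dom.height:.0f}",
        fill="#ffffff", stroke="#444444",
    )

    radius = pop.radius
    par = pop.is_parenchyma
    rel = np.zeros(len(pop))
    if par.any():
        rel[par] = np.clip(pop.deformation[par] / d_max, 0.0, 1.0)
    par_colors = _ramp(rel, *ramp)

    for i in range(len(pop)):
        x, y = pop.position[i]
        attrs = {
            "cx": f"{x:.2f}",
            "cy": f"{dom.height - y:.2f}",  # y up in tissue coordinates
            "r": f"{max(radius[i], 0.1):.2f}",
        }
        if pop.type[i] == TYPE_TUMOR:
            fill = TUMOR_COLORS[int(pop.phase[i])]
            if pop.phase[i] < PHASE_APOPTOTIC and pop.pressure[i] > p2:
                fill = PRESSURE_OVERRIDE_COLOR
            attrs["fill"] = fill
        else:
            if pop.phase[i] == PHASE_APOPTOTIC:
                attrs["fill"] = PARENCHYMA_DEAD_COLOR
            else:
                attrs["fill"] = par_colors[i]
                if pop.deformation[i] > OUTLINE_FRACTION * d_max:
                    attrs["stroke"] = "#000000"
                    attrs["stroke-width"] = "1"
        ET.SubElement(svg, "circle", **attrs)

    _add_legend(svg, dom)
    _add_scale_bar(svg, dom)
    return ET.tostring(svg, encoding="unicode")


def _add_legend(svg: ET.Element, dom) -> None:
    entries = [
        ("Ki67- (quiescent)", TUMOR_COLORS[PHASE_KI67_NEG]),
        ("Ki67+ premitotic", TUMOR_COLORS[PHASE_KI67_PRE]),
        ("Ki67+ postmitotic", TUMOR_COLORS[PHASE_KI67_POST]),
        ("apoptotic", TUMOR_COLORS[PHASE_APOPTOTIC]),
        ("necrotic", TUMOR_COLORS[PHASE_NECROTIC]),
        ("pressure > p2", PRESSURE_OVERRIDE_COLOR),
        ("parenchyma (strained)", PARENCHYMA_RAMP[1]),
        ("parenchyma apoptotic", PARENCHYMA_DEAD_COLOR),
    ]
    x0 = dom.width + 20
    for k, (label, color) in enumerate(entries):
        y = 20 + 22 * k
        ET.SubElement(
            svg, "circle", cx=f"{x0:.0f}", cy=f"{y:.0f}", r="7", fill=color,
            stroke="#444444",
        )
        txt = ET.SubElement(
            svg, "text", x=f"{x0 + 14:.0f}", y=f"{y + 4:.0f}",
            **{"font-size": "12", "font-family": "sans-serif"},
        )
        txt.text = label


def _add_scale_bar(svg: ET.Element, dom) -> None:
    bar = min(500.0, dom.width / 4.0)
    y = dom.height + 20
    ET.SubElement(
        svg, "line", x1="10", y1=f"{y:.0f}", x2=f"{10 + bar:.0f}", y2=f"{y:.0f}",
        stroke="#000000", **{"stroke-width": "3"},
    )
    txt = ET.SubElement(
        svg, "text", x=f"{15 + bar:.0f}", y=f"{y + 4:.0f}",
        **{"font-size": "12", "font-family": "sans-serif"},
    )
    txt.text = f"{bar:.0f} um"


# ---------------------------------------------------------------------------
# tables

def write_cell_table(state, path: str | Path) -> None:
    """Per-agent CSV; anchor fields are empty for tumor cells."""
    pop = state.pop
    par = pop.is_parenchyma
    anchor_x = np.where(par, pop.anchor[:, 0], np.nan)
    anchor_y = np.where(par, pop.anchor[:, 1], np.nan)
    deform = np.where(par, pop.deformation, np.nan)
    df = pd.DataFrame(
        {
            "id": pop.ids,
            "type": np.where(pop.type == TYPE_TUMOR, "tumor", "parenchyma"),
            "phase": [PHASE_NAMES[int(p)] for p in pop.phase],
            "x": pop.position[:, 0],
            "y": pop.position[:, 1],
            "radius": pop.radius,
            "pressure": pop.pressure,
            "oxygen": pop.oxygen,
            "anchor_x": anchor_x,
            "anchor_y": anchor_y,
            "deformation": deform,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# oxygen-versus-depth curves (static tumor study)

def oxygen_vs_depth(
    field,
    pop,
    bin_width: float = 20.0,
    outside_extent: float = 200.0,
) -> pd.DataFrame:
    """Mean oxygen binned by distance from each tumor's edge.

    Tumor voxels (>= 1 tumor-cell center) are labeled into connected
    components; depth is positive into a tumor and negative outside (outside
    voxels are assigned to their nearest tumor, out to ``outside_extent``).
    Returns a long frame (tumor, depth, mean_pO2, std_pO2, n_voxels).
    """
    occ = np.zeros((field.ny, field.nx), dtype=bool)
    tum = pop.is_tumor
    if tum.any():
        iy, ix = field.voxel_indices(pop.position[tum])
        occ[iy, ix] = True
    labels, n_comp = ndimage.label(occ)
    if n_comp == 0:
        return pd.DataFrame(
            columns=["tumor", "depth", "mean_pO2", "std_pO2", "n_voxels"]
        )

    # nearest tumor voxel (hence component) for every outside voxel
    dist_out, (ny_idx, nx_idx) = ndimage.distance_transform_edt(
        ~occ, return_indices=True
    )
    nearest_comp = labels[ny_idx, nx_idx]

    rows = []
    for comp in range(1, n_comp + 1):
        mask = labels == comp
        depth_in = (ndimage.distance_transform_edt(mask) - 0.5) * field.dx
        sel_in = mask
        depths = depth_in[sel_in]
        vals = field.values[sel_in]
        sel_out = (~occ) & (nearest_comp == comp) & (dist_out * field.dx <= outside_extent)
        depths = np.concatenate([depths, -(dist_out[sel_out] - 0.5) * field.dx])
        vals = np.concatenate([vals, field.values[sel_out]])
        bins = np.floor(depths / bin_width).astype(int)
        for b in np.unique(bins):
            v = vals[bins == b]
            rows.append(
                {
                    "tumor": comp,
                    "depth": (b + 0.5) * bin_width,
                    "mean_pO2": float(v.mean()),
                    "std_pO2": float(v.std()),
                    "n_voxels": int(len(v)),
                }
            )
    return pd.DataFrame(rows)


def tumor_oxygen_summary(field, pop) -> pd.DataFrame:
    """Per-tumor mean and standard deviation of oxygen over its voxels."""
    occ = np.zeros((field.ny, field.nx), dtype=bool)
    tum = pop.is_tumor
    if tum.any():
        iy, ix = field.voxel_indices(pop.position[tum])
        occ[iy, ix] = True
    labels, n_comp = ndimage.label(occ)
    rows = []
    for comp in range(1, n_comp + 1):
        mask = labels == comp
        vals = field.values[mask]
        area = float(mask.sum()) * field.dx**2
        rows.append(
            {
                "tumor": comp,
                "area": area,
                "equivalent_diameter": 2.0 * np.sqrt(area / np.pi),
                "mean_pO2": float(vals.mean()),
                "std_pO2": float(vals.std()),
                "min_pO2": float(vals.min()),
            }
        )
    return pd.DataFrame(rows)


def viable_depth(curves: pd.DataFrame, tumor: int, threshold: float) -> float | None:
    """Smallest interior depth whose bin-mean oxygen is below ``threshold``.

    Returns None when the tumor never drops below the threshold (fully
    viable).
    """
    sub = curves[(curves["tumor"] == tumor) & (curves["depth"] > 0)].sort_values("depth")
    below = sub[sub["mean_pO2"] < threshold]
    if below.empty:
        return None
    return float(below["depth"].iloc[0])
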