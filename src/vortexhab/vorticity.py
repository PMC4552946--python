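"""Cross-sectional vorticity metrics.

The streamwise vorticity of a cell is the discrete curl of the in-plane
velocity, |dv_z/dy - dv_y/dz|, taken as a magnitude cell by cell. The
cross-sectional mean is its area-weighted average over the wetted section,
equivalently circulation / wetted area. Section summaries report the mean per
transverse third of the wetted top width (left / middle / right, facing
downstream) for the full section and for the near-bed layer (bed to 1.3 m
above the bed), with the section "mean" defined as the unweighted average of
the three band means; the area-weighted whole-section mean is exposed
separately as :func:`area_weighted_mean`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError, EmptyFieldError, UndefinedMeanError
from .grids import CrossSectionGrid

__all__ = [
    "VorticityField",
    "SectionSummary",
    "compute_cell_vorticity",
    "select_layer",
    "mean_vorticity",
    "area_weighted_mean",
    "mean_of_bands",
    "subregion_summary",
    "summarize_reach",
    "DEFAULT_LAYER_HEIGHT",
    "LAYERS",
]

#: Near-bed layer height, m: the band from the bed to 1.3 m above it where
#: high-intensity vorticity concentrates in natural spawning sections.
DEFAULT_LAYER_HEIGHT = 1.3

LAYERS = ("full", "bottom_1p3m")


@dataclass
class VorticityField:
    """Per-cell vorticity magnitudes on a grid.

    ``omega`` is zero on dry cells; ``cell_area`` is the uniform cell area.
    """

    omega: np.ndarray
    wet: np.ndarray
    cell_area: float

    @property
    def wetted_area(self) -> float:
        """A_TOT: wetted cross-sectional area, m^2."""
        return float(self.wet.sum()) * self.cell_area

    @property
    def circulation(self) -> float:
        """Gamma: sum of omega * cell area over wet cells, m^2/s."""
        return float(self.omega[self.wet].sum()) * self.cell_area

    def wet_values(self) -> np.ndarray:
        """Vorticity magnitudes of the wet cells, flattened."""
        return self.omega[self.wet]


@dataclass
class SectionSummary:
    """Left/middle/right and overall mean vorticity of one transect (1/s).

    A band with no wet cells is reported as None and excluded from the mean.
    """

    section_id: str
    layer: str
    left: float | None
    middle: float | None
    right: float | None
    mean: float
    label: str | None = None


def compute_cell_vorticity(grid: CrossSectionGrid) -> VorticityField:
    """Discrete per-cell vorticity magnitude |dv_z/dy - dv_y/dz|, 1/s.

    dv_z/dy uses the forward difference toward the right neighbour and
    dv_y/dz the one-sided difference toward the cell above; where that
    neighbour is dry or absent, the opposite one-sided difference is used,
    and if neither neighbour is wet the derivative is taken as zero. Only
    wet cells enter any stencil.
    """
    wet = grid.wet
    if not wet.any():
        raise EmptyFieldError("grid has no wet cells")
    vy, vz = grid.v_y, grid.v_z

    def shifted(a: np.ndarray, axis: int, step: int) -> np.ndarray:
        out = np.zeros_like(a)
        if axis == 1:
            if step == 1:
                out[:, :-1] = a[:, 1:]
            else:
                out[:, 1:] = a[:, :-1]
        else:
            if step == 1:
                out[:-1, :] = a[1:, :]
            else:
                out[1:, :] = a[:-1, :]
        return out

    def one_sided(v: np.ndarray, axis: int, h: float) -> np.ndarray:
        ahead_wet = shifted(wet, axis, 1).astype(bool)
        behind_wet = shifted(wet, axis, -1).astype(bool)
        fwd = (shifted(v, axis, 1) - v) / h
        bwd = (v - shifted(v, axis, -1)) / h
        return np.where(
            wet & ahead_wet, fwd, np.where(wet & behind_wet, bwd, 0.0)
        )

    dvz_dy = one_sided(vz, axis=1, h=grid.dy)
    dvy_dz = one_sided(vy, axis=0, h=grid.dz)
    omega = np.abs(dvz_dy - dvy_dz)
    omega[~wet] = 0.0
    return VorticityField(omega=omega, wet=wet.copy(), cell_area=grid.cell_area)


def select_layer(grid: CrossSectionGrid, height: float) -> np.ndarray:
    """Mask of wet cells within ``height`` metres of the local bed.

    Membership is by cell center: z_bed(y) <= z <= z_bed(y) + height. The
    bottom-most wet cell of each column is always included, so the layer
    degenerates to the near-bed row (not the empty set) as height -> 0+.
    """
    if height <= 0:
        raise ContractError("layer height must be positive")
    wet = grid.wet
    zz = grid.z[:, None]
    mask = wet & (zz <= grid.z_bed[None, :] + height)
    # bottom-most wet cell per column
    has_wet = wet.any(axis=0)
    bottom = np.where(has_wet, wet.argmax(axis=0), 0)
    mask[bottom[has_wet], np.nonzero(has_wet)[0]] = True
    return mask


def mean_vorticity(field: VorticityField, mask: np.ndarray) -> float:
    """Area-weighted mean vorticity over the masked wet cells: sum(omega dA)/sum(dA)."""
    sel = np.asarray(mask, dtype=bool) & field.wet
    n = int(sel.sum())
    if n == 0:
        raise UndefinedMeanError("mask selects no wet cells")
    return float(field.omega[sel].sum() * field.cell_area / (n * field.cell_area))


def area_weighted_mean(
    field: VorticityField, grid: CrossSectionGrid, layer: str = "full",
    layer_height: float = DEFAULT_LAYER_HEIGHT,
) -> float:
    """Whole-section area-weighted mean vorticity (circulation / area) for a layer."""
    mask = grid.wet if layer == "full" else select_layer(grid, layer_height)
    return mean_vorticity(field, mask)


def mean_of_bands(bands: Iterable[float | None]) -> float:
    """Section mean as the unweighted average of the available band means."""
    vals = [b for b in bands if b is not None]
    if not vals:
        raise UndefinedMeanError("no band has wet cells")
    return float(sum(vals) / len(vals))


def subregion_summary(
    field: VorticityField,
    grid: CrossSectionGrid,
    layer: str = "full",
    section_id: str = "",
    label: str | None = None,
    layer_height: float = DEFAULT_LAYER_HEIGHT,
) -> SectionSummary:
    """Left/middle/right band means within a layer, plus their average.

    The wetted top width is split into three equal-width transverse bands;
    cells are assigned by y center. An empty band is reported as None with a
    warning and excluded from the mean.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    wet_cols = grid.wet.any(axis=0)
    if not wet_cols.any():
        raise EmptyFieldError("grid has no wet columns")
    y_lo = grid.y[wet_cols].min() - grid.dy / 2.0
    y_hi = grid.y[wet_cols].max() + grid.dy / 2.0
    edges = np.linspace(y_lo, y_hi, 4)
    layer_mask = grid.wet if layer == "full" else select_layer(grid, layer_height)
    yy = np.broadcast_to(grid.y[None, :], grid.wet.shape)
    bands: list[float | None] = []
    for name, lo, hi in (
        ("left", edges[0], edges[1]),
        ("middle", edges[1], edges[2]),
        ("right", edges[2], edges[3]),
    ):
        band = layer_mask & (yy >= lo) & (yy < hi if name != "right" else yy <= hi)
        if not band.any():
            warnings.warn(
                f"section {section_id or '<unnamed>'}: {name} band has no wet "
                f"cells in layer {layer}; excluded from the section mean",
                stacklevel=2,
            )
            bands.append(None)
        else:
            bands.append(mean_vorticity(field, band))
    return SectionSummary(
        section_id=section_id,
        layer=layer,
        left=bands[0],
        middle=bands[1],
        right=bands[2],
        mean=mean_of_bands(bands),
        label=label,
    )


def summarize_reach(
    sections: Sequence[tuple[str, str, CrossSectionGrid]],
    layer_height: float = DEFAULT_LAYER_HEIGHT,
) -> tuple[list[SectionSummary], dict]:
    """Summaries (both layers) for every section plus per-group aggregates.

    ``sections`` is a sequence of (section_id, label, grid) with labels in
    {spawning, transition, nonspawning}. Aggregates hold, per layer, the
    per-label average of section means and the spawning/non-spawning ratio.
    """
    from .synthetic import SCENARIO_LABELS
    from .vorticity import compute_cell_vorticity  # self-import for clarity

    summaries: list[SectionSummary] = []
    for section_id, label, grid in sections:
        if label not in SCENARIO_LABELS:
            raise ValueError(f"unknown section label {label!r} for {section_id}")
        field = compute_cell_vorticity(grid)
        for layer in LAYERS:
            summaries.append(
                subregion_summary(
                    field, grid, layer=layer, section_id=section_id,
                    label=label, layer_height=layer_height,
                )
            )
    aggregates: dict = {"group_means": {}, "ratio_spawning_to_nonspawning": {}}
    for layer in LAYERS:
        by_label: dict[str, float] = {}
        for label in SCENARIO_LABELS:
            means = [
                s.mean for s in summaries if s.label == label and s.layer == layer
            ]
            if means:
                by_label[label] = float(np.mean(means))
        aggregates["group_means"][layer] = by_label
        if "spawning" in by_label and "nonspawning" in by_label:
            aggregates["ratio_spawning_to_nonspawning"][layer] = (
                by_label["spawning"] / by_label["nonspawning"]
            )
    return summaries, aggregates
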