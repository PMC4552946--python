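"""Synthetic cross-section flow fields with controlled vorticity content.

Mountain-river spawning transects are emulated as a compound channel (main
channel flanked by berm shelves) carrying strong coherent vortices near the
bed, while non-spawning transects are V-shaped with a near-uniform weak shear.
Vortices follow the Lamb-Oseen model (Gaussian vorticity core, everywhere
smooth) or optionally the Rankine model (solid-body core, irrotational
exterior), so the exact curl of every generated field is available in closed
form and serves as the oracle for the finite-difference vorticity metrics.

A uniform vertical shear in ``v_y`` provides the background vorticity floor
observed in post-processed field/CFD transects (non-spawning sections report
~0.100 1/s rather than zero); its curl equals the shear rate exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, ContractError, EmptyWettedAreaError
from .grids import CrossSectionGrid

__all__ = [
    "BedProfile",
    "VortexSpec",
    "ScenarioSpec",
    "build_section_geometry",
    "evaluate_velocity",
    "analytic_vorticity",
    "generate_scenario",
    "calibrate_circulation",
    "calibrate_spec",
    "SCENARIO_LABELS",
    "DEFAULT_TARGET_MEANS",
    "NONSPAWNING_BASELINE",
]

SCENARIO_LABELS = ("spawning", "transition", "nonspawning")

#: Background vorticity floor of non-spawning transects, 1/s.
NONSPAWNING_BASELINE = 0.10

#: Default cross-sectional mean vorticity each scenario label is calibrated to,
#: 1/s. Spawning and transition values sit inside the 0.17-0.35 1/s interval
#: reported for natural spawning grounds and just below it, respectively.
DEFAULT_TARGET_MEANS = {
    "spawning": 0.26,
    "transition": 0.17,
    "nonspawning": NONSPAWNING_BASELINE,
}


@dataclass(frozen=True)
class BedProfile:
    """Parametric bed elevation profile z_bed(y) of a transect.

    ``compound`` is a trapezoidal main channel flanked by berm shelves,
    ``vee`` a symmetric V with the invert at mid-width, ``flat`` a rectangle.
    Fractions are of total width; the berm sits at
    ``berm_height_fraction * max_depth`` above the invert.
    """

    kind: str
    width: float
    max_depth: float
    berm_fraction: float = 0.25
    berm_height_fraction: float = 0.55
    transition_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.kind not in ("compound", "vee", "flat"):
            raise ValueError(f"unknown bed kind {self.kind!r}")
        if self.width <= 0 or self.max_depth <= 0:
            raise ValueError("width and max_depth must be positive")
        if self.kind == "compound" and not (
            0 < self.berm_fraction
            and 0 < self.transition_fraction
            and 2 * (self.berm_fraction + self.transition_fraction) < 1
        ):
            raise ValueError("compound berms and transitions must leave a main channel")

    def z_bed(self, y):
        """Bed elevation above the invert at transverse coordinate(s) y, m."""
        y = np.asarray(y, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(y)
        if self.kind == "vee":
            return self.max_depth * np.abs(2.0 * y / self.width - 1.0)
        b = self.berm_fraction * self.width
        t = self.transition_fraction * self.width
        hb = self.berm_height_fraction * self.max_depth
        # distance from the nearer bank
        d = np.minimum(y, self.width - y)
        out = np.full_like(y, hb)
        on_slope = (d > b) & (d < b + t)
        out[on_slope] = hb * (1.0 - (d[on_slope] - b) / t)
        out[d >= b + t] = 0.0
        return out

    def wetted_area_analytic(self, water_surface: float) -> float:
        """Closed-form wetted area below ``water_surface``, m^2."""
        ws = float(water_surface)
        if ws <= 0:
            return 0.0
        if self.kind == "flat":
            return self.width * ws
        if self.kind == "vee":
            if ws >= self.max_depth:
                return self.width * ws - self.width * self.max_depth / 2.0
            # triangle: top width scales linearly with depth
            return self.width * ws * ws / (2.0 * self.max_depth)
        b = self.berm_fraction * self.width
        t = self.transition_fraction * self.width
        hb = self.berm_height_fraction * self.max_depth
        w_center = self.width - 2.0 * (b + t)
        area = w_center * ws
        if ws >= hb:
            area += 2.0 * (t * ws - t * hb / 2.0)  # full trapezoidal transitions
            area += 2.0 * b * (ws - hb)  # rectangles over the berms
        else:
            area += 2.0 * (t * ws * ws / (2.0 * hb))  # partially wet slopes
        return area


@dataclass(frozen=True)
class VortexSpec:
    """One coherent vortex: center (y, z) in m, signed circulation in m^2/s,
    core radius in m, and the velocity model."""

    center: tuple[float, float]
    circulation: float
    core_radius: float
    model: str = "lamb_oseen"

    def __post_init__(self) -> None:
        if self.core_radius <= 0:
            raise ValueError("core_radius must be positive")
        if self.model not in ("lamb_oseen", "rankine"):
            raise ValueError(f"unknown vortex model {self.model!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full recipe for one synthetic transect; the seed makes it bit-reproducible."""

    label: str
    bed: BedProfile
    vortices: tuple[VortexSpec, ...]
    base_velocity: tuple[float, float] = (0.0, 0.0)
    background_shear: float = 0.0
    noise_sd: float = 0.0
    ny: int = 60
    nz: int = 36
    water_surface: float = 1.8
    seed: int = 0
    achieved_mean: float | None = None  # recorded by calibration, informational

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise ValueError(f"unknown scenario label {self.label!r}")
        if self.ny < 4 or self.nz < 4:
            raise ValueError("grid resolution must be at least 4x4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "vortices", tuple(self.vortices))
        for v in self.vortices:
            yc, zc = v.center
            if not (0.0 <= yc <= self.bed.width and 0.0 <= zc <= self.water_surface):
                raise ValueError("vortex center outside the section bounding box")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "bed": {
                "kind": self.bed.kind,
                "width": self.bed.width,
                "max_depth": self.bed.max_depth,
                "berm_fraction": self.bed.berm_fraction,
                "berm_height_fraction": self.bed.berm_height_fraction,
                "transition_fraction": self.bed.transition_fraction,
            },
            "vortices": [
                {
                    "center": list(v.center),
                    "circulation": v.circulation,
                    "core_radius": v.core_radius,
                    "model": v.model,
                }
                for v in self.vortices
            ],
            "base_velocity": list(self.base_velocity),
            "background_shear": self.background_shear,
            "noise_sd": self.noise_sd,
            "ny": self.ny,
            "nz": self.nz,
            "water_surface": self.water_surface,
            "seed": self.seed,
        }
        if self.achieved_mean is not None:
            d["achieved_mean"] = self.achieved_mean
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            label=d["label"],
            bed=BedProfile(**d["bed"]),
            vortices=tuple(
                VortexSpec(
                    center=tuple(v["center"]),
                    circulation=v["circulation"],
                    core_radius=v["core_radius"],
                    model=v.get("model", "lamb_oseen"),
                )
                for v in d["vortices"]
            ),
            base_velocity=tuple(d.get("base_velocity", (0.0, 0.0))),
            background_shear=d.get("background_shear", 0.0),
            noise_sd=d.get("noise_sd", 0.0),
            ny=d.get("ny", 60),
            nz=d.get("nz", 36),
            water_surface=d["water_surface"],
            seed=d.get("seed", 0),
            achieved_mean=d.get("achieved_mean"),
        )


# ---------------------------------------------------------------------------
# geometry and velocity evaluation
# ---------------------------------------------------------------------------


def build_section_geometry(
    bed: BedProfile, ny: int, nz: int, water_surface: float
) -> CrossSectionGrid:
    """Discretise a transect on an ny x nz cell-centered grid with zero velocity.

    The grid spans ``[0, width] x [0, water_surface]``; a cell is wet when its
    center lies at or above the bed (and, by construction, below the surface).
    """
    if water_surface <= 0:
        raise EmptyWettedAreaError("water surface is at or below the channel invert")
    dy = bed.width / ny
    dz = water_surface / nz
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    z_bed = bed.z_bed(y)
    wet = z[:, None] >= z_bed[None, :]
    if not wet.any():
        raise EmptyWettedAreaError("no cell center lies between bed and surface")
    zeros = np.zeros((nz, ny))
    return CrossSectionGrid(
        y=y,
        z=z,
        dy=dy,
        dz=dz,
        v_y=zeros.copy(),
        v_z=zeros.copy(),
        wet=wet,
        z_bed=z_bed,
        water_surface=water_surface,
    )


def _vortex_velocity(v: VortexSpec, yy: np.ndarray, zz: np.ndarray):
    """In-plane (v_y, v_z) induced by one vortex at cell centers (yy, zz)."""
    dyv = yy - v.center[0]
    dzv = zz - v.center[1]
    r2 = dyv * dyv + dzv * dzv
    rc2 = v.core_radius**2
    if v.model == "lamb_oseen":
        u = r2 / rc2
        # g = v_theta / r; finite-core limit Gamma/(2 pi rc^2) at r -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(u < 1e-12, 1.0 / rc2, -np.expm1(-u) / np.where(u > 0, r2, 1.0))
        g *= v.circulation / (2.0 * math.pi)
    else:  # rankine
        with np.errstate(divide="ignore"):
            g = np.where(r2 < rc2, 1.0 / rc2, 1.0 / np.where(r2 > 0, r2, 1.0))
        g *= v.circulation / (2.0 * math.pi)
    return -g * dzv, g * dyv


def evaluate_velocity(spec: ScenarioSpec, grid: CrossSectionGrid) -> CrossSectionGrid:
    """Fill the grid's wet cells with the scenario's velocity field.

    The field is the uniform base flow, plus the background shear
    ``v_y -= shear * (z - water_surface)`` (curl = shear, the vorticity floor),
    plus vortex contributions, plus seeded isotropic Gaussian noise. Dry cells
    keep zero velocity.
    """
    out = grid.copy()
    yy, zz = out.meshgrid()
    v_y = np.full_like(yy, spec.base_velocity[0])
    v_z = np.full_like(yy, spec.base_velocity[1])
    v_y -= spec.background_shear * (zz - spec.water_surface)
    for v in spec.vortices:
        dvy, dvz = _vortex_velocity(v, yy, zz)
        v_y += dvy
        v_z += dvz
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v_y += rng.normal(0.0, spec.noise_sd, size=v_y.shape)
        v_z += rng.normal(0.0, spec.noise_sd, size=v_z.shape)
    v_y[~out.wet] = 0.0
    v_z[~out.wet] = 0.0
    out.v_y = v_y
    out.v_z = v_z
    return out


def analytic_vorticity(spec: ScenarioSpec, y, z):
    """Exact curl dv_z/dy - dv_y/dz of the noise-free scenario field at (y, z).

    Signed; the background shear contributes its constant rate and each
    Lamb-Oseen vortex contributes ``Gamma/(pi rc^2) exp(-r^2/rc^2)``
    (Rankine: ``Gamma/(pi rc^2)`` inside the core, zero outside).
    """
    if spec.noise_sd > 0:
        raise ContractError("analytic vorticity is defined for noise-free scenarios")
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    omega = np.full(np.broadcast(y, z).shape, spec.background_shear, dtype=float)
    for v in spec.vortices:
        r2 = (y - v.center[0]) ** 2 + (z - v.center[1]) ** 2
        rc2 = v.core_radius**2
        peak = v.circulation / (math.pi * rc2)
        if v.model == "lamb_oseen":
            omega = omega + peak * np.exp(-r2 / rc2)
        else:
            omega = omega + np.where(r2 < rc2, peak, 0.0)
    return omega if omega.shape else float(omega)


# ---------------------------------------------------------------------------
# scenario templates and calibration
# ---------------------------------------------------------------------------


def _template(label: str, rng: np.random.Generator) -> ScenarioSpec:
    """Label-specific scenario template with seeded vortex placement jitter.

    Spawning: compound channel, five near-bed vortices (strongest mid-channel,
    centers within 1.3 m of the bed). Transition: intermediate compound shape,
    three weaker vortices. Non-spawning: V-shaped section, two faint vortices
    over a 0.098 1/s shear so calibration can land the 0.10 1/s baseline.
    """
    if label == "spawning":
        bed = BedProfile("compound", width=30.0, max_depth=2.2)
        ws = 1.8
        y0 = np.array([12.0, 13.8, 15.2, 16.5, 18.0]) + rng.uniform(-0.6, 0.6, 5)
        gam = np.array([1.2, 1.8, 2.2, 1.8, 1.2])
        dz_bed = rng.uniform(0.25, 1.1, 5)
        rc = rng.uniform(0.28, 0.45, 5)
        shear = NONSPAWNING_BASELINE
        base = (0.3, 0.0)
    elif label == "transition":
        bed = BedProfile(
            "compound",
            width=34.0,
            max_depth=2.6,
            berm_fraction=0.18,
            berm_height_fraction=0.45,
            transition_fraction=0.12,
        )
        ws = 2.2
        y0 = np.array([14.0, 17.0, 20.0]) + rng.uniform(-0.6, 0.6, 3)
        gam = np.array([1.2, 1.6, 1.2])
        dz_bed = rng.uniform(0.3, 1.2, 3)
        rc = rng.uniform(0.30, 0.50, 3)
        shear = NONSPAWNING_BASELINE
        base = (0.25, 0.0)
    elif label == "nonspawning":
        bed = BedProfile("vee", width=40.0, max_depth=3.2)
        ws = 2.6
        y0 = np.array([18.5, 21.5]) + rng.uniform(-0.8, 0.8, 2)
        gam = np.array([0.3, 0.3])
        dz_bed = rng.uniform(0.4, 1.2, 2)
        rc = rng.uniform(0.35, 0.55, 2)
        shear = 0.098
        base = (0.2, 0.0)
    else:
        raise ValueError(f"unknown scenario label {label!r}")
    z_bed = bed.z_bed(y0)
    vortices = tuple(
        VortexSpec(center=(float(yc), float(zb + dz)), circulation=float(g), core_radius=float(r))
        for yc, zb, dz, g, r in zip(y0, z_bed, dz_bed, gam, rc)
    )
    return ScenarioSpec(
        label=label,
        bed=bed,
        vortices=vortices,
        base_velocity=base,
        background_shear=shear,
        water_surface=ws,
    )


def _measured_mean(spec: ScenarioSpec) -> float:
    """Cross-sectional mean vorticity of the noise-free realisation of spec."""
    from .vorticity import compute_cell_vorticity, mean_vorticity

    quiet = replace(spec, noise_sd=0.0)
    grid = build_section_geometry(quiet.bed, quiet.ny, quiet.nz, quiet.water_surface)
    grid = evaluate_velocity(quiet, grid)
    fld = compute_cell_vorticity(grid)
    return mean_vorticity(fld, grid.wet)


def _scale_circulations(spec: ScenarioSpec, m: float) -> ScenarioSpec:
    return replace(
        spec,
        vortices=tuple(replace(v, circulation=v.circulation * m) for v in spec.vortices),
    )


def calibrate_spec(spec: ScenarioSpec, target_mean: float, tol: float = 1e-3) -> ScenarioSpec:
    """Scale all vortex circulations by one multiplier until the measured
    cross-sectional mean vorticity is within relative ``tol`` of ``target_mean``.

    Root finding brackets the multiplier on [0, 2^20]; an unreachable target
    (the floor alone already exceeds it, or the template saturates below it)
    raises :class:`CalibrationError`.
    """
    if target_mean <= 0:
        raise ContractError("target_mean must be positive")
    if tol <= 0:
        raise ContractError("calibration tolerance must be positive")

    def f(m: float) -> float:
        return _measured_mean(_scale_circulations(spec, m)) - target_mean

    f1 = f(1.0)
    if abs(f1) <= tol * target_mean:
        return replace(spec, achieved_mean=f1 + target_mean)
    f0 = f(0.0)
    if f0 > tol * target_mean:
        raise CalibrationError(
            f"background floor alone gives mean {f0 + target_mean:.4f} > target {target_mean}"
        )
    lo, flo = 0.0, f0
    hi, fhi = 1.0, f1
    while fhi < 0:
        lo, flo = hi, fhi
        hi *= 2.0
        if hi > 2**20:
            raise CalibrationError("target mean unreachable with this vortex template")
        fhi = f(hi)
    m_star = brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    out = _scale_circulations(spec, m_star)
    achieved = _measured_mean(out)
    if abs(achieved - target_mean) > tol * target_mean:
        raise CalibrationError(
            f"calibration stalled at mean {achieved:.5f} for target {target_mean}"
        )
    return replace(out, achieved_mean=achieved)


def generate_scenario(
    label: str, params: dict | None = None, seed: int = 0
) -> ScenarioSpec:
    """Build a calibrated scenario for one habitat label.

    ``params`` may override ``target_mean`` (default per label, see
    :data:`DEFAULT_TARGET_MEANS`), ``noise_sd``, ``ny``, ``nz`` and
    ``calibration_tol``. The seed jitters vortex placement (so sections of the
    same label differ) and seeds the noise generator; the same seed reproduces
    the scenario, and its grids, bit for bit.
    """
    params = dict(params or {})
    target = params.pop("target_mean", DEFAULT_TARGET_MEANS[label])
    tol = params.pop("calibration_tol", 1e-3)
    noise_sd = params.pop("noise_sd", 0.0)
    ny = params.pop("ny", None)
    nz = params.pop("nz", None)
    if params:
        raise ValueError(f"unknown scenario parameters: {sorted(params)}")
    rng = np.random.default_rng(seed)
    spec = _template(label, rng)
    if ny is not None or nz is not None:
        spec = replace(spec, ny=ny or spec.ny, nz=nz or spec.nz)
    spec = replace(spec, seed=seed)
    spec = calibrate_spec(spec, target, tol)
    return replace(spec, noise_sd=noise_sd)


def calibrate_circulation(
    label: str, target_mean: float, tol: float = 1e-3, seed: int = 0
) -> ScenarioSpec:
    """Calibrate the label's template so its mean vorticity hits ``target_mean``."""
    rng = np.random.default_rng(seed)
    spec = replace(_template(label, rng), seed=seed)
    return calibrate_spec(spec, target_mean, tol)
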