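"""Synthetic blood-smear scenes and cohort tables with known ground truth.

Scenes emulate 1000x-magnification Wright-Giemsa fields: a bright pale
background, round pale-red anucleate RBCs (default mean radius 3.75 um,
i.e. mean true area near 44 um^2) with a lighter central-pallor region,
darker nucleated cells whose purple nucleus dominates their gray level,
optional touching pairs, and additive Gaussian pixel noise. Cells are
rendered as anti-aliased ellipses — the measurement pipeline only ever
sees the 2-D projection of a cell, so the biconcave 3-D shape is not
modeled.

Cohort tables mirror the statistical structure of the study population:
four groups (normal and the three cytopenic diseases AA, MDS, MA) with
per-subject mean areas drawn from the group mean/SD, lognormal for the
groups whose clinical area distributions were non-normal (AA, MDS), and
CBC indices (MCV/MCH/MCHC/RDW) drawn independently of area by default —
encoding the observed absence of area-CBC correlation; a correlation knob
exists for power studies.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import SmearImage

__all__ = [
    "SceneSpec",
    "CellTruth",
    "GroundTruth",
    "PlacementError",
    "generate_scene",
    "generate_cohort",
    "GROUPS",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SDS",
    "DEFAULT_N_SUBJECTS",
    "DEFAULT_SKEWED_GROUPS",
    "DEFAULT_CBC_PARAMS",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed within the retry budget."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic smear field of view."""

    height: int = 640
    width: int = 640
    microns_per_pixel: float = 0.1
    n_rbc: int = 20
    n_nucleated: int = 2
    rbc_radius_mean_um: float = 3.75
    rbc_radius_sd_um: float = 0.2
    nucleated_radius_mean_um: float = 5.0
    nucleated_radius_sd_um: float = 0.3
    ellipticity_max: float = 1.05  # axis ratio drawn uniformly in [1, e_max]
    fraction_touching: float = 0.0
    touch_distance_factor: float = 0.95  # center distance / (r1 + r2) for touching pairs
    background_color: tuple[int, int, int] = (245, 240, 240)
    rbc_color: tuple[int, int, int] = (230, 160, 150)
    nucleated_cytoplasm_color: tuple[int, int, int] = (170, 160, 200)
    nucleus_color: tuple[int, int, int] = (90, 60, 130)
    central_pallor_depth: float = 0.35  # 0 = none, 1 = background-colored center
    central_pallor_radius_fraction: float = 0.5
    nucleus_radius_fraction: float = 0.85  # nucleus occupies >= 50% of the cell area
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rbc < 0 or self.n_nucleated < 0:
            raise ValueError("cell counts must be >= 0")
        if self.ellipticity_max < 1:
            raise ValueError("ellipticity_max must be >= 1")
        if not (0 <= self.central_pallor_depth <= 1):
            raise ValueError("central_pallor_depth must be in [0, 1]")
        if not (0 <= self.fraction_touching <= 1):
            raise ValueError("fraction_touching must be in [0, 1]")


@dataclass
class CellTruth:
    center_px: tuple[float, float]  # (row, col)
    semi_major_um: float
    semi_minor_um: float
    angle_rad: float
    true_area_um2: float
    label: str  # "rbc" | "nucleated"
    touching: bool = False


@dataclass
class GroundTruth:
    cells: list[CellTruth] = field(default_factory=list)

    @property
    def n_rbc(self) -> int:
        return sum(1 for c in self.cells if c.label == "rbc")

    @property
    def n_nucleated(self) -> int:
        return sum(1 for c in self.cells if c.label == "nucleated")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_px": [c.center_px[0] for c in self.cells],
                "col_px": [c.center_px[1] for c in self.cells],
                "semi_major_um": [c.semi_major_um for c in self.cells],
                "semi_minor_um": [c.semi_minor_um for c in self.cells],
                "true_area_um2": [c.true_area_um2 for c in self.cells],
                "label": [c.label for c in self.cells],
                "touching": [c.touching for c in self.cells],
            }
        )


def _cell_window(h, w, center, a_px, b_px, angle):
    """Bounding-box slice plus the normalized elliptical radius field in it."""
    ext = max(a_px, b_px) + 3
    r0 = max(int(center[0] - ext), 0)
    r1 = min(int(center[0] + ext) + 2, h)
    c0 = max(int(center[1] - ext), 0)
    c1 = min(int(center[1] + ext) + 2, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    d = np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)
    return (slice(r0, r1), slice(c0, c1)), d


def _paint_cell(img, window, d, r_eff_px, color_field):
    """Alpha-composite a cell onto img; ~1 px anti-aliased edge."""
    alpha = np.clip(0.5 + (1.0 - d) * r_eff_px, 0.0, 1.0)
    img[window] = img[window] * (1 - alpha)[..., None] + color_field * alpha[..., None]


def generate_scene(spec: SceneSpec) -> tuple[SmearImage, GroundTruth]:
    """Render one field of view and its exhaustive ground truth.

    Cells are placed by rejection sampling with a minimum 3 px gap; when
    ``fraction_touching`` > 0, the prescribed fraction of RBCs is placed
    as touching pairs (center distance below the sum of radii) so the
    merged-clump handling can be exercised.

    Raises
    ------
    PlacementError
        If a cell cannot be placed in 2000 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mpp = spec.microns_per_pixel
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.array(spec.background_color, float)

    placed: list[tuple[float, float, float]] = []  # (row, col, radius_px)
    truth = GroundTruth()

    def draw_radius_um(mean, sd):
        r = rng.normal(mean, sd) if sd > 0 else mean
        return max(r, 0.5)

    def try_place(r_px, attach_to=None):
        margin = r_px + 2
        if margin > h - margin or margin > w - margin:
            raise PlacementError(
                f"cell of radius {r_px:.1f} px does not fit a {h}x{w} field"
            )
        for _ in range(2000):
            if attach_to is None:
                row = rng.uniform(margin, h - margin)
                col = rng.uniform(margin, w - margin)
            else:
                ar, ac, arad = attach_to
                theta = rng.uniform(0, 2 * math.pi)
                dist = spec.touch_distance_factor * (arad + r_px)
                row, col = ar + dist * math.sin(theta), ac + dist * math.cos(theta)
                if not (margin <= row <= h - margin and margin <= col <= w - margin):
                    continue
            ok = True
            for pr, pc, prad in placed:
                if attach_to is not None and (pr, pc, prad) == attach_to:
                    continue
                if math.hypot(row - pr, col - pc) < r_px + prad + 3:
                    ok = False
                    break
            if ok:
                return row, col
        raise PlacementError(
            f"could not place a cell of radius {r_px:.1f} px in {h}x{w} field"
        )

    def render_rbc(center, r_um, touching):
        e = rng.uniform(1.0, spec.ellipticity_max)
        a_um = r_um * math.sqrt(e)
        b_um = r_um / math.sqrt(e)
        angle = rng.uniform(0, math.pi)
        a_px, b_px = a_um / mpp, b_um / mpp
        window, d = _cell_window(h, w, center, a_px, b_px, angle)
        bg = np.array(spec.background_color, float)
        rbc = np.array(spec.rbc_color, float)
        color_field = np.broadcast_to(rbc, d.shape + (3,))
        if spec.central_pallor_depth > 0:
            pallor = np.clip(
                0.5 + (spec.central_pallor_radius_fraction - d) * min(a_px, b_px),
                0.0,
                1.0,
            )
            lerp = spec.central_pallor_depth * pallor
            color_field = rbc + lerp[..., None] * (bg - rbc)
        _paint_cell(img, window, d, min(a_px, b_px), color_field)
        truth.cells.append(
            CellTruth(
                center_px=center,
                semi_major_um=a_um,
                semi_minor_um=b_um,
                angle_rad=angle,
                true_area_um2=math.pi * a_um * b_um,
                label="rbc",
                touching=touching,
            )
        )

    def render_nucleated(center, r_um):
        angle = rng.uniform(0, math.pi)
        r_px = r_um / mpp
        window, d = _cell_window(h, w, center, r_px, r_px, angle)
        cyto = np.array(spec.nucleated_cytoplasm_color, float)
        nuc = np.array(spec.nucleus_color, float)
        nuc_alpha = np.clip(0.5 + (spec.nucleus_radius_fraction - d) * r_px, 0.0, 1.0)
        color_field = cyto + nuc_alpha[..., None] * (nuc - cyto)
        _paint_cell(img, window, d, r_px, color_field)
        truth.cells.append(
            CellTruth(
                center_px=center,
                semi_major_um=r_um,
                semi_minor_um=r_um,
                angle_rad=angle,
                true_area_um2=math.pi * r_um * r_um,
                label="nucleated",
                touching=False,
            )
        )

    n_touching_pairs = int(round(spec.fraction_touching * spec.n_rbc / 2))
    n_single_rbc = spec.n_rbc - 2 * n_touching_pairs

    for _ in range(n_touching_pairs):
        r1 = draw_radius_um(spec.rbc_radius_mean_um, spec.rbc_radius_sd_um)
        r2 = draw_radius_um(spec.rbc_radius_mean_um, spec.rbc_radius_sd_um)
        c1 = try_place(r1 / mpp + r2 / mpp)  # reserve room for the pair
        anchor = (c1[0], c1[1], r1 / mpp)
        placed.append(anchor)
        c2 = try_place(r2 / mpp, attach_to=anchor)
        placed.append((c2[0], c2[1], r2 / mpp))
        render_rbc(c1, r1, touching=True)
        render_rbc(c2, r2, touching=True)

    for _ in range(n_single_rbc):
        r = draw_radius_um(spec.rbc_radius_mean_um, spec.rbc_radius_sd_um)
        c = try_place(r / mpp)
        placed.append((c[0], c[1], r / mpp))
        render_rbc(c, r, touching=False)

    for _ in range(spec.n_nucleated):
        r = draw_radius_um(spec.nucleated_radius_mean_um, spec.nucleated_radius_sd_um)
        c = try_place(r / mpp)
        placed.append((c[0], c[1], r / mpp))
        render_nucleated(c, r)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    smear = SmearImage(
        pixels=pixels,
        microns_per_pixel=mpp,
        source_id=f"synthetic-scene-seed{spec.seed}",
    )
    return smear, truth


# --- cohort generation -----------------------------------------------------

GROUPS = ("normal", "AA", "MDS", "MA")

#: Group-level mean / SD of per-subject mean RBC area (um^2) and subject
#: counts matching the study population structure.
DEFAULT_GROUP_MEANS = {"normal": 44.19, "AA": 43.47, "MDS": 45.86, "MA": 52.87}
DEFAULT_GROUP_SDS = {"normal": 3.88, "AA": 4.37, "MDS": 6.42, "MA": 7.68}
DEFAULT_N_SUBJECTS = {"normal": 25, "AA": 25, "MDS": 68, "MA": 64}
#: Groups whose clinical area distributions were non-normal.
DEFAULT_SKEWED_GROUPS = frozenset({"AA", "MDS"})

#: Per-group CBC index (mean, sd): MCV fL, MCH pg, MCHC g/L, RDW %.
DEFAULT_CBC_PARAMS = {
    "normal": {"mcv_fl": (89.94, 5.87), "mch_pg": (29.60, 2.33), "mchc_g_per_l": (328.44, 9.93), "rdw_percent": (13.76, 1.66)},
    "AA": {"mcv_fl": (95.82, 14.25), "mch_pg": (33.22, 5.12), "mchc_g_per_l": (347.05, 15.01), "rdw_percent": (15.20, 3.91)},
    "MDS": {"mcv_fl": (100.80, 13.33), "mch_pg": (33.21, 4.92), "mchc_g_per_l": (328.90, 14.59), "rdw_percent": (18.90, 5.45)},
    "MA": {"mcv_fl": (123.26, 13.28), "mch_pg": (41.91, 4.93), "mchc_g_per_l": (340.84, 11.47), "rdw_percent": (19.16, 4.84)},
}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_cohort(
    group_means: dict[str, float] | None = None,
    group_sds: dict[str, float] | None = None,
    n_subjects: dict[str, int] | None = None,
    cbc_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    skewed_groups=DEFAULT_SKEWED_GROUPS,
    area_mcv_correlation: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-subject cohort table.

    Per-subject mean areas are normal (lognormal for ``skewed_groups``,
    moment-matched to the same mean/SD); CBC indices are normal and, by
    default, independent of area. ``area_mcv_correlation`` injects a
    Gaussian copula correlation between area and MCV for power studies.

    Returns a DataFrame with columns subject_id, group, mean_area_um2,
    mcv_fl, mch_pg, mchc_g_per_l, rdw_percent.
    """
    group_means = dict(DEFAULT_GROUP_MEANS if group_means is None else group_means)
    group_sds = dict(DEFAULT_GROUP_SDS if group_sds is None else group_sds)
    n_subjects = dict(DEFAULT_N_SUBJECTS if n_subjects is None else n_subjects)
    cbc_params = DEFAULT_CBC_PARAMS if cbc_params is None else cbc_params
    for g in group_means:
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        if group_sds[g] < 0:
            raise ValueError(f"group {g!r} has negative SD")
        if n_subjects[g] < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")

    rng = np.random.default_rng(seed)
    rows = []
    for g in GROUPS:
        if g not in group_means:
            continue
        m, s, n = group_means[g], group_sds[g], n_subjects[g]
        z_area = rng.standard_normal(n)
        if g in skewed_groups and s > 0:
            mu, sigma = _lognormal_params(m, s)
            areas = np.exp(mu + sigma * z_area)
        else:
            areas = m + s * z_area
        for i in range(n):
            row = {
                "subject_id": f"{g}-{i + 1:03d}",
                "group": g,
                "mean_area_um2": float(areas[i]),
            }
            for idx, (cm, cs) in cbc_params.get(g, {}).items():
                z = rng.standard_normal()
                if idx == "mcv_fl" and area_mcv_correlation != 0:
                    rho = area_mcv_correlation
                    z = rho * z_area[i] + math.sqrt(1 - rho * rho) * z
                row[idx] = float(cm + cs * z)
            rows.append(row)
    return pd.DataFrame(rows)
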