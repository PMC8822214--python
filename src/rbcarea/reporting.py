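"""Pipeline orchestration, configuration and report assembly.

``measure_image`` runs the full per-image chain (HSV conversion, Otsu
segmentation, optional edge refinement, outer-contour extraction,
S_mean-relative single-cell selection, gray-ratio classification,
enclosing-circle area with roundness recall). ``run_measure`` pools
multiple fields of view per subject into one smear summary;
``run_stats`` runs the cohort workflow (pairwise group comparisons,
per-group CV, area-CBC correlations, and single/combined-marker ROC)
on a per-subject table. Every number in the report is produced by an
operation in the science modules — nothing is computed only here.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import area as area_mod
from . import classification as classify_mod
from . import cohort_stats as stats_mod
from . import imaging
from . import segmentation as seg_mod
from .classification import CellClass, CellRecord
from .imaging import SmearImage
from .segmentation import ContourSetSummary, ContourStatus

__all__ = [
    "RunConfig",
    "CalibrationConfig",
    "SegmentationConfig",
    "ClassificationConfig",
    "AreaConfig",
    "StatsConfig",
    "measure_image",
    "run_measure",
    "run_stats",
    "COHORT_COLUMNS",
    "CBC_COLUMNS",
]

logger = logging.getLogger("rbcarea")

COHORT_COLUMNS = ["subject_id", "group", "mean_area_um2"]
CBC_COLUMNS = ["mcv_fl", "mch_pg", "mchc_g_per_l", "rdw_percent"]
DISEASE_GROUPS = ("AA", "MDS", "MA")


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class CalibrationConfig:
    microns_per_pixel: float = 0.1

    def __post_init__(self):
        if not (np.isfinite(self.microns_per_pixel) and self.microns_per_pixel > 0):
            raise ValueError("microns_per_pixel must be finite and > 0")


@dataclass
class SegmentationConfig:
    noise_floor_um2: float = seg_mod.NOISE_FLOOR_UM2
    pending_ceiling_um2: float = seg_mod.PENDING_CEILING_UM2
    a: float = seg_mod.AREA_RATIO_LOW
    b: float = seg_mod.AREA_RATIO_HIGH
    convexity_min: float = seg_mod.CONVEXITY_MIN
    edge_refine: bool = True

    def __post_init__(self):
        if not (0 < self.a < 1 < self.b):
            raise ValueError(f"need 0 < a < 1 < b, got a={self.a}, b={self.b}")
        if not (0 < self.convexity_min <= 1):
            raise ValueError("convexity_min must be in (0, 1]")


@dataclass
class ClassificationConfig:
    ratio_threshold: float = classify_mod.RATIO_THRESHOLD

    def __post_init__(self):
        if not (0 < self.ratio_threshold < 2):
            raise ValueError("ratio_threshold out of its documented domain (0, 2)")


@dataclass
class AreaConfig:
    roundness_min: float = area_mod.ROUNDNESS_MIN
    include_non_recall: bool = False

    def __post_init__(self):
        if not (0 < self.roundness_min < 1):
            raise ValueError("roundness_min must be in (0, 1)")


@dataclass
class StatsConfig:
    alpha_normality: float = stats_mod.ALPHA_NORMALITY
    holm_adjust: bool = False

    def __post_init__(self):
        if not (0 < self.alpha_normality < 1):
            raise ValueError("alpha_normality must be in (0, 1)")


@dataclass
class RunConfig:
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    area: AreaConfig = field(default_factory=AreaConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build from nested section dicts; unknown keys are rejected."""
        sections = {
            "calibration": CalibrationConfig,
            "segmentation": SegmentationConfig,
            "classification": ClassificationConfig,
            "area": AreaConfig,
            "stats": StatsConfig,
        }
        kwargs = {}
        for key, value in data.items():
            if key in sections:
                kwargs[key] = _from_dict(sections[key], value)
            elif key in ("seed", "verbosity"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


def measure_image(
    img: SmearImage, config: RunConfig | None = None
) -> tuple[list[CellRecord], ContourSetSummary]:
    """Run the full per-image measurement chain on one field of view.

    Returns the effective single-cell records (classified, with circle
    geometry, Pmean, Si and — for recall RBCs — Sr filled in) and the
    contour census including S_mean.
    """
    cfg = config or RunConfig()
    t0 = time.perf_counter()
    hsv = imaging.rgb_to_hsv(img)
    gray = imaging.rgb_to_gray(img)
    mask = seg_mod.otsu_segment(hsv)
    if cfg.segmentation.edge_refine:
        mask = seg_mod.edge_refine(mask, gray)
    contours = seg_mod.extract_outer_contours(mask, img.microns_per_pixel)
    parts = seg_mod.flag_pending(
        contours,
        noise_floor_um2=cfg.segmentation.noise_floor_um2,
        pending_ceiling_um2=cfg.segmentation.pending_ceiling_um2,
    )
    s_mean = seg_mod.compute_s_mean(parts["candidate"])
    effective = seg_mod.select_effective_contours(
        parts["candidate"],
        s_mean,
        a=cfg.segmentation.a,
        b=cfg.segmentation.b,
        convexity_min=cfg.segmentation.convexity_min,
    )

    cells = [
        CellRecord(contour=ct, g=classify_mod.mean_gray_of_cell(gray, ct))
        for ct in effective
    ]
    if cells:
        mg = classify_mod.cohort_mean_gray(cells)
        for cell in cells:
            cell.mg = mg
            cell.g_ratio = cell.g / mg
            cell.cell_class = classify_mod.classify_cell(
                cell.g, mg, cfg.classification.ratio_threshold
            )
            center, radius = area_mod.min_enclosing_circle(cell.contour)
            cell.circle_center = (float(center[0]), float(center[1]))
            cell.circle_radius_px = radius
            ratios, cell.pmean = area_mod.roundness_profile(cell.contour, center, radius)
            cell.si_um2 = area_mod.area_si(radius, img.microns_per_pixel)
            cell.recall = area_mod.is_recall_rbc(
                ratios,
                cell.si_um2,
                s_mean,
                a=cfg.segmentation.a,
                b=cfg.segmentation.b,
                roundness_min=cfg.area.roundness_min,
            )
            if cell.recall or cfg.area.include_non_recall:
                cell.sr_um2 = area_mod.area_sr(cell.si_um2, cell.pmean)
    summary = seg_mod.summarize_contours(contours, s_mean)
    if cfg.verbosity >= 1:
        logger.info(
            "%s: %d contours (%d effective) in %.2f s",
            img.source_id, summary.n_total, summary.n_effective,
            time.perf_counter() - t0,
        )
    return cells, summary


def _load_input(item, cfg: RunConfig) -> SmearImage:
    if isinstance(item, SmearImage):
        return item
    return imaging.load_image(item, cfg.calibration.microns_per_pixel)


def run_measure(
    images_by_subject: dict[str, list], config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Measure every subject's fields of view and pool them per subject.

    ``images_by_subject`` maps subject id to a list of image paths (or
    in-memory :class:`SmearImage` objects). Cells from all of a subject's
    images are pooled before the smear summary. A failing image is logged
    and recorded in the manifest; the subject is marked failed only if no
    image succeeds.

    Returns ``(summary_frame, manifest)``.
    """
    cfg = config or RunConfig()
    rows = []
    manifest: dict = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "images": {},
        "failures": [],
    }
    for subject, items in images_by_subject.items():
        cells: list[CellRecord] = []
        ok = 0
        for item in items:
            label = getattr(item, "source_id", None) or str(item)
            try:
                img = _load_input(item, cfg)
                img_cells, summary = measure_image(img, cfg)
                cells.extend(img_cells)
                ok += 1
                manifest["images"][label] = {
                    "subject": subject,
                    "n_contours": summary.n_total,
                    "n_effective": summary.n_effective,
                    "n_merged": summary.n_merged,
                    "s_mean_um2": summary.s_mean_um2,
                }
            except Exception as exc:
                logger.error("image %s of subject %s failed: %s", label, subject, exc)
                manifest["failures"].append(
                    {"subject": subject, "image": label, "error": str(exc)}
                )
        if ok == 0:
            rows.append(
                {"subject_id": subject, "n_rbc_measured": 0, "mean_area_um2": None,
                 "sd_area_um2": None, "cv_percent": None, "failed": True}
            )
            continue
        summ = area_mod.summarize_smear(
            cells, subject, include_non_recall=cfg.area.include_non_recall
        )
        rows.append(
            {
                "subject_id": summ.subject_id,
                "n_rbc_measured": summ.n_rbc_measured,
                "mean_area_um2": summ.mean_area_um2,
                "sd_area_um2": summ.sd_area_um2,
                "cv_percent": summ.cv_percent,
                "failed": False,
            }
        )
    return pd.DataFrame(rows), manifest


def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def run_stats(cohort, config: RunConfig | None = None) -> dict:
    """Cohort statistics report from a per-subject table.

    ``cohort`` is a CSV path or DataFrame with columns subject_id, group,
    mean_area_um2 and optionally the CBC indices. The report contains all
    pairwise group comparisons, per-group CV, per-group area-CBC
    correlations, and per-disease ROC records for area, MCV and the
    combined logistic predicted probability (disease vs normal, raw
    orientation: higher score counts toward the disease).
    """
    cfg = config or RunConfig()
    df = pd.read_csv(cohort) if not isinstance(cohort, pd.DataFrame) else cohort.copy()
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicated subject_id values: {dupes}")
    bad_groups = sorted(set(df["group"]) - {"normal", "AA", "MDS", "MA"})
    if bad_groups:
        raise ValueError(f"unknown group labels: {bad_groups}")

    report: dict = {"n_subjects": {g: int(n) for g, n in df["group"].value_counts().items()}}
    groups = [g for g in ("normal", "AA", "MDS", "MA") if g in set(df["group"])]
    by_group = {g: df[df["group"] == g] for g in groups}

    # per-group location/scale and CV of per-subject mean areas
    report["group_summaries"] = {}
    for g in groups:
        v = by_group[g]["mean_area_um2"].to_numpy(float)
        gs = stats_mod.GroupSummary.from_values(v)
        report["group_summaries"][g] = {
            **asdict(gs),
            "cv_percent": stats_mod.coefficient_of_variation(gs.mean, gs.sd),
        }

    # pairwise comparisons
    comparisons = {}
    pair_keys, pair_pvals = [], []
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            x = by_group[g1]["mean_area_um2"].to_numpy(float)
            y = by_group[g2]["mean_area_um2"].to_numpy(float)
            if len(x) < 3 or len(y) < 3:
                continue
            res = stats_mod.compare_groups(x, y, cfg.stats.alpha_normality)
            key = f"{g1}_vs_{g2}"
            comparisons[key] = asdict(res)
            pair_keys.append(key)
            pair_pvals.append(res.p_value)
    if cfg.stats.holm_adjust and pair_pvals:
        for key, p_adj in zip(pair_keys, _holm(pair_pvals)):
            comparisons[key]["p_value_holm"] = p_adj
    report["comparisons"] = comparisons

    # area vs CBC correlations, per group
    correlations: dict = {}
    available_cbc = [c for c in CBC_COLUMNS if c in df.columns]
    for skipped in set(CBC_COLUMNS) - set(available_cbc):
        logger.warning("cohort table lacks %s: correlations/ROC for it skipped", skipped)
    for g in groups:
        sub = by_group[g]
        correlations[g] = {}
        for idx in available_cbc:
            pair = sub[["mean_area_um2", idx]].dropna()
            if len(pair) < 4:
                continue
            method, r, p = stats_mod.correlate(
                pair["mean_area_um2"], pair[idx], cfg.stats.alpha_normality
            )
            correlations[g][idx] = {"method": method, "r": r, "p_value": p}
    report["correlations"] = correlations

    # per-disease ROC: disease vs normal
    roc: dict = {}
    if "normal" in by_group:
        normal = by_group["normal"]
        for disease in DISEASE_GROUPS:
            if disease not in by_group:
                continue
            sub = pd.concat([by_group[disease], normal])
            labels = (sub["group"] == disease).to_numpy()
            entry = {}
            scores_area = sub["mean_area_um2"].to_numpy(float)
            entry["area"] = asdict(stats_mod.roc_auc(scores_area, labels, marker="area"))
            if "mcv_fl" in sub.columns and sub["mcv_fl"].notna().all():
                scores_mcv = sub["mcv_fl"].to_numpy(float)
                entry["mcv"] = asdict(stats_mod.roc_auc(scores_mcv, labels, marker="mcv"))
                comb = stats_mod.combined_predictor(scores_area, scores_mcv, labels)
                rr = stats_mod.roc_auc(comb.probabilities, labels, marker="predicted_probability")
                entry["predicted_probability"] = {**asdict(rr), "separated_fit": comb.separated}
            roc[disease] = entry
    report["roc"] = roc
    return json.loads(json.dumps(report, sort_keys=True))  # plain JSON types, stable order
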