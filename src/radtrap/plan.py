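"""Target-volume construction, simplified dose engines and DVH reporting.

Probability maps become a gross target volume (GTV) by thresholding inside
the prostate capsule; planning target volumes (PTV) add a physical margin,
cropped to the capsule and away from the urethra. Three plan types are
compared:

* ``P_WH`` — whole-gland homogeneous plan (prostate at prescription),
* ``P_RF`` — radiomics-based focal plan (GTV + 5 mm margin only),
* ``P_WF`` — whole gland plus a focal boost to GTV + 2 mm.

The brachytherapy dose engine is a deliberately simplified point-source
kernel (air-kerma strength x dose-rate constant x inverse square x a
tabulated radial dose function, integrated over the full decay of a
permanent I-125 implant); the EBRT engine paints distance-weighted coverage
fields from a small set of coplanar beam directions. Neither reproduces a
commercial optimizer — they exist to make the *comparisons between plan
types* executable, not to produce clinical dose values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import EmptyStructureError, StructureSet, VolumeGrid
from .classify import ProbabilityMap

log = logging.getLogger(__name__)

BRACHY_PRESCRIPTION_GY = 145.0
BRACHY_BOOST_GY = 217.5  # focal escalation to 150 % of prescription
EBRT_PRESCRIPTION_GY = 79.2
EBRT_BOOST_GY = 85.8
FOCAL_MARGIN_MM = 5.0
BOOST_MARGIN_MM = 2.0
MIN_COMPONENT_CC = 0.05

# Permanent-implant I-125 source model (point-source approximation):
# air-kerma strength U = cGy cm^2 / h; dose-rate constant Lambda in
# cGy / (h U); dose integrated over full decay (1.44 * half-life).
AIR_KERMA_STRENGTH_U = 0.5
DOSE_RATE_CONSTANT = 0.965  # cGy / (h U)
I125_HALF_LIFE_H = 59.4 * 24.0
# radial dose function g(r), r in cm (broadly representative of published
# I-125 seed data; linearly interpolated, constant beyond the table)
_RADIAL_R_CM = np.array([0.10, 0.25, 0.50, 0.75, 1.00, 1.50, 2.00, 3.00, 4.00, 5.00, 6.00, 7.00])
_RADIAL_G = np.array([1.055, 1.078, 1.071, 1.042, 1.000, 0.926, 0.842, 0.681, 0.537, 0.420, 0.323, 0.247])

BRACHY_METRICS = ("D90", "V100", "V150", "V200", "D10", "D1cc", "D2cc", "mean")
EBRT_METRICS = ("Dmin_0.03cc", "Dmax_0.03cc", "mean")
BRACHY_STRUCTURES = ("prostate", "ptv", "urethra", "rectum", "bladder")
EBRT_STRUCTURES = ("prostate", "ptv", "bladder", "rectum", "penile_bulb", "femoral_heads")


class SchemaError(ValueError):
    """Raised when required structures or metric schemas do not match."""


# ---------------------------------------------------------------------------
# Target volumes


@dataclass
class TargetVolumes:
    gtv: np.ndarray
    ptv: np.ndarray
    threshold: float
    margin_mm: float


def threshold_to_gtv(pmap: ProbabilityMap, threshold: float, capsule: np.ndarray,
                     min_component_cc: float = MIN_COMPONENT_CC) -> np.ndarray:
    """Binary cancer volume: p >= threshold inside the capsule, de-speckled.

    Connected components smaller than ``min_component_cc`` are removed. An
    empty result is legal (logged, not fatal): the focal plans are then
    skipped upstream.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    capsule = np.asarray(capsule, dtype=bool)
    raw = (pmap.values >= threshold) & pmap.mask & capsule
    if not raw.any():
        log.warning("empty target: no voxel reaches threshold %.2f", threshold)
        return raw
    labels, n = ndimage.label(raw)
    voxel_cc = pmap.grid.voxel_volume_cc()
    keep = np.zeros_like(raw)
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() * voxel_cc >= min_component_cc:
            keep |= comp
    if not keep.any():
        log.warning("empty target after removing components below %.2f cc", min_component_cc)
    return keep


def expand_margin(gtv: np.ndarray, margin_mm: float, capsule: np.ndarray,
                  exclusions: Sequence[np.ndarray] = (), spacing=(1.0, 1.0, 1.0),
                  exclusion_margin_mm: float = 3.0) -> np.ndarray:
    """Euclidean dilation by ``margin_mm``, cropped to the capsule.

    Exclusion masks (e.g. the urethra) are grown by ``exclusion_margin_mm``
    and subtracted after cropping, so escalated dose regions keep a standoff
    from the spared structure rather than merely not overlapping it.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    gtv = np.asarray(gtv, dtype=bool)
    if not gtv.any():
        raise EmptyStructureError("GTV is empty")
    if margin_mm == 0:
        out = gtv.copy()
    else:
        dist = ndimage.distance_transform_edt(~gtv, sampling=spacing)
        out = dist <= margin_mm
    out &= np.asarray(capsule, dtype=bool)
    for excl in exclusions:
        excl = np.asarray(excl, dtype=bool)
        if exclusion_margin_mm > 0:
            excl = ndimage.distance_transform_edt(
                ~excl, sampling=spacing) <= exclusion_margin_mm
        out &= ~excl
    return out


def make_targets(pmap: ProbabilityMap, capsule: np.ndarray, threshold: float = 0.5,
                 margin_mm: float = FOCAL_MARGIN_MM,
                 exclusions: Sequence[np.ndarray] = ()) -> TargetVolumes:
    gtv = threshold_to_gtv(pmap, threshold, capsule)
    if gtv.any():
        ptv = expand_margin(gtv, margin_mm, capsule, exclusions, pmap.grid.spacing)
    else:
        ptv = gtv.copy()
    return TargetVolumes(gtv, ptv, threshold, margin_mm)


def suggest_threshold(pmap: ProbabilityMap, truth: np.ndarray) -> float:
    """Youden-index threshold suggestion from ground truth (advisory only).

    The operating threshold is a clinical choice; this helper merely reports
    the J-maximizing point of the phantom ROC and is never applied silently.
    """
    from sklearn.metrics import roc_curve

    labels = np.asarray(truth, dtype=bool)[pmap.mask]
    fpr, tpr, thr = roc_curve(labels, pmap.masked_values())
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


# ---------------------------------------------------------------------------
# Brachytherapy dose engine


@dataclass
class SeedConfiguration:
    """I-125 seed positions (mm), strengths (U) and needle grouping."""

    positions: np.ndarray  # (n, 3) physical mm
    strengths: np.ndarray  # (n,) air-kerma strength U
    needle_ids: np.ndarray  # (n,) int; seeds sharing a needle are collinear

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.needle_ids = np.asarray(self.needle_ids, dtype=int)
        if np.any(self.strengths <= 0):
            raise ValueError("seed strengths must be positive")
        if not (len(self.positions) == len(self.strengths) == len(self.needle_ids)):
            raise ValueError("positions, strengths and needle ids must align")

    @property
    def n_seeds(self) -> int:
        return len(self.positions)

    @property
    def n_needles(self) -> int:
        return len(np.unique(self.needle_ids)) if self.n_seeds else 0

    def write_table(self, path) -> None:
        df = pd.DataFrame(self.positions, columns=["x_mm", "y_mm", "z_mm"])
        df["strength_U"] = self.strengths
        df["needle"] = self.needle_ids
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _dose_per_seed_gy(r_mm: np.ndarray) -> np.ndarray:
    """Total decay-integrated dose (Gy) of one unit-table seed at r."""
    r_cm = np.asarray(r_mm, dtype=float) / 10.0
    g = np.interp(r_cm, _RADIAL_R_CM, _RADIAL_G)
    rate_cgy_h = DOSE_RATE_CONSTANT * (1.0 / np.maximum(r_cm, 1e-6)) ** 2 * g
    total_cgy = rate_cgy_h * 1.443 * I125_HALF_LIFE_H
    return total_cgy / 100.0


def compute_seed_dose(seeds: SeedConfiguration, geometry: VolumeGrid,
                      points: Optional[np.ndarray] = None) -> VolumeGrid:
    """Superpose the point-source kernel of every seed on the grid.

    Distances are capped below at half the smallest voxel dimension to
    avoid the kernel singularity. With ``points`` given, returns the dose
    at those physical points instead (used by the greedy placer).
    """
    if seeds.n_seeds == 0:
        raise ValueError("need at least one seed")
    lo = np.asarray(geometry.origin) - np.asarray(geometry.spacing)
    hi = geometry.voxel_to_physical(np.asarray(geometry.shape) - 1) + np.asarray(geometry.spacing)
    if np.any(seeds.positions < lo) or np.any(seeds.positions > hi):
        raise ValueError("seed position outside the dose grid")
    if points is None:
        xs, ys, zs = geometry.physical_grid()
        pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    else:
        pts = np.atleast_2d(points)
    rmin = min(geometry.spacing) / 2.0
    dose = np.zeros(len(pts))
    for pos, sk in zip(seeds.positions, seeds.strengths):
        r = np.linalg.norm(pts - pos, axis=1)
        dose += sk * _dose_per_seed_gy(np.maximum(r, rmin))
    if points is not None:
        return dose
    return VolumeGrid(dose.reshape(geometry.shape), geometry.spacing, geometry.origin, "DOSE")


def place_seeds(target: np.ndarray, prescription_gy: float, geometry: VolumeGrid,
                needle_spacing_mm: float = 5.0, seed_spacing_mm: float = 5.0,
                strength_u: float = AIR_KERMA_STRENGTH_U,
                max_seeds: int = 250, avoid: Optional[np.ndarray] = None,
                avoid_margin_mm: float = 4.0) -> SeedConfiguration:
    """Greedy seed placement on a template grid until D90 meets prescription.

    Candidate positions form a rectangular needle template (in-plane pitch
    ``needle_spacing_mm``) with seeds every ``seed_spacing_mm`` along each
    needle, restricted to the target and kept ``avoid_margin_mm`` away from
    the ``avoid`` structure (urethral sparing). Each step adds the unused
    candidate closest to the coldest target voxel; the result is
    deterministic. If the budget is exhausted a coverage shortfall is logged
    and the configuration is returned as-is.
    """
    target = np.asarray(target, dtype=bool)
    if not target.any():
        raise EmptyStructureError("cannot place seeds in an empty target")
    seedable = target
    if avoid is not None and avoid_margin_mm > 0:
        near = ndimage.distance_transform_edt(
            ~np.asarray(avoid, dtype=bool), sampling=geometry.spacing) <= avoid_margin_mm
        if (target & ~near).any():
            seedable = target & ~near
    idx = np.argwhere(target)
    tgt_pts = idx * np.asarray(geometry.spacing) + np.asarray(geometry.origin)
    seed_idx = np.argwhere(seedable)
    seed_pts = seed_idx * np.asarray(geometry.spacing) + np.asarray(geometry.origin)
    lo = seed_pts.min(axis=0)
    hi = seed_pts.max(axis=0)
    xs = np.arange(lo[0], hi[0] + 1e-6, needle_spacing_mm)
    ys = np.arange(lo[1], hi[1] + 1e-6, needle_spacing_mm)
    zs = np.arange(lo[2], hi[2] + 1e-6, seed_spacing_mm)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    cand = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    # keep candidates whose containing voxel is in the target
    vox = np.round((cand - np.asarray(geometry.origin)) / np.asarray(geometry.spacing)).astype(int)
    ok = np.all((vox >= 0) & (vox < np.asarray(geometry.shape)), axis=1)
    cand, vox = cand[ok], vox[ok]
    inside = seedable[vox[:, 0], vox[:, 1], vox[:, 2]]
    cand = cand[inside]
    if len(cand) == 0:  # tiny target: fall back to its centroid
        cand = seed_pts.mean(axis=0, keepdims=True)
    used = np.zeros(len(cand), dtype=bool)
    dose = np.zeros(len(tgt_pts))
    chosen: List[int] = []
    rmin = min(geometry.spacing) / 2.0
    n_tgt = len(tgt_pts)
    d90_rank = max(0, n_tgt - int(np.ceil(0.9 * n_tgt)))  # ascending index

    def current_d90():
        return np.partition(dose, d90_rank)[d90_rank]

    while len(chosen) < max_seeds:
        if current_d90() >= prescription_gy:
            break
        cold = tgt_pts[int(np.argmin(dose))]
        free = np.nonzero(~used)[0]
        if len(free) == 0:
            break
        pick = free[int(np.argmin(np.linalg.norm(cand[free] - cold, axis=1)))]
        used[pick] = True
        chosen.append(pick)
        r = np.linalg.norm(tgt_pts - cand[pick], axis=1)
        dose += strength_u * _dose_per_seed_gy(np.maximum(r, rmin))
    if current_d90() < prescription_gy:
        log.warning("seed budget exhausted: D90 %.1f Gy < prescription %.1f Gy",
                    current_d90(), prescription_gy)
    pos = cand[chosen]
    # needles group seeds sharing an (x, y) template position
    needle_keys = {tuple(np.round(p[:2], 3)) for p in pos}
    needle_map = {k: i for i, k in enumerate(sorted(needle_keys))}
    needles = np.array([needle_map[tuple(np.round(p[:2], 3))] for p in pos], dtype=int)
    return SeedConfiguration(pos, np.full(len(pos), strength_u), needles)


# ---------------------------------------------------------------------------
# EBRT surrogate dose engine


def ebrt_field(target: np.ndarray, geometry: VolumeGrid, n_beams: int = 7,
               penumbra_mm: float = 4.0) -> np.ndarray:
    """Normalized coverage field from coplanar beams aimed at the target.

    Each beam contributes 1 inside the target's projected aperture (with a
    linear penumbra) at every depth along the beam; the mean over beams
    yields a conformal-looking normalized field with graded falloff.
    """
    target = np.asarray(target, dtype=bool)
    if not target.any():
        raise EmptyStructureError("EBRT target is empty")
    xs, ys, zs = geometry.physical_grid()
    pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    tgt = np.argwhere(target) * np.asarray(geometry.spacing) + np.asarray(geometry.origin)
    iso = tgt.mean(axis=0)
    acc = np.zeros(len(pts))
    pitch = 1.0  # mm resolution of the aperture plane
    for b in range(n_beams):
        ang = np.pi * b / n_beams
        perp = np.array([-np.sin(ang), np.cos(ang), 0.0])
        # aperture coordinates: lateral (perp) and axial (z)
        tgt_u = (tgt - iso) @ perp
        tgt_z = tgt[:, 2] - iso[2]
        pts_u = (pts - iso) @ perp
        pts_z = pts[:, 2] - iso[2]
        # rasterize the projected footprint, then a Euclidean distance map
        u0, u1 = tgt_u.min() - 2 * penumbra_mm, tgt_u.max() + 2 * penumbra_mm
        z0, z1 = tgt_z.min() - 2 * penumbra_mm, tgt_z.max() + 2 * penumbra_mm
        nu = int(np.ceil((u1 - u0) / pitch)) + 1
        nz = int(np.ceil((z1 - z0) / pitch)) + 1
        ap = np.zeros((nu, nz), dtype=bool)
        iu = np.clip(np.round((tgt_u - u0) / pitch).astype(int), 0, nu - 1)
        iz = np.clip(np.round((tgt_z - z0) / pitch).astype(int), 0, nz - 1)
        ap[iu, iz] = True
        dist = ndimage.distance_transform_edt(~ap, sampling=(pitch, pitch))
        cu = np.clip((pts_u - u0) / pitch, 0, nu - 1)
        cz = np.clip((pts_z - z0) / pitch, 0, nz - 1)
        d = ndimage.map_coordinates(dist, np.stack([cu, cz]), order=1, mode="nearest")
        outside = ((pts_u < u0) | (pts_u > u1) | (pts_z < z0) | (pts_z > z1))
        d = np.where(outside, np.maximum(d, penumbra_mm), d)
        acc += np.clip(1.0 - d / penumbra_mm, 0.0, 1.0)
    return (acc / n_beams).reshape(geometry.shape)


def ebrt_dose(target: np.ndarray, geometry: VolumeGrid, prescription_gy: float,
              n_beams: int = 7) -> VolumeGrid:
    """Coverage field scaled so the target's D95 equals the prescription."""
    fieldv = ebrt_field(target, geometry, n_beams)
    d95 = np.percentile(fieldv[np.asarray(target, dtype=bool)], 5)
    scale = prescription_gy / max(d95, 1e-9)
    return VolumeGrid(fieldv * scale, geometry.spacing, geometry.origin, "DOSE")


# ---------------------------------------------------------------------------
# DVH metrics


@dataclass
class DVHRecord:
    structure: str
    metrics: Dict[str, float]
    flags: List[str] = field(default_factory=list)


def dvh_metrics(dose: VolumeGrid, structure: np.ndarray, prescription_gy: float,
                metrics: Sequence[str] = BRACHY_METRICS, name: str = "structure") -> DVHRecord:
    """Voxel-volume-weighted DVH summary of one structure.

    Dx is the minimum dose of the hottest x % of the structure volume; Vy
    the percent volume receiving at least y % of prescription; Dxcc the
    minimum dose of the hottest x cm^3 (Dmin_xcc the maximum dose of the
    coldest x cm^3). When the structure is smaller than a requested
    absolute volume the metric covers the whole structure and is flagged.
    """
    structure = np.asarray(structure, dtype=bool)
    if not structure.any():
        raise EmptyStructureError(f"structure {name!r} is empty")
    doses = np.sort(dose.values[structure])[::-1]
    n = len(doses)
    voxel_cc = dose.voxel_volume_cc()
    flags: List[str] = []

    def d_percent(x):
        k = min(n - 1, max(0, int(np.ceil(x / 100.0 * n)) - 1))
        return float(doses[k])

    def d_cc(cc, hottest=True):
        nonlocal flags
        k = int(np.ceil(cc / voxel_cc))
        if k > n:
            flags.append(f"structure smaller than {cc} cc; metric over full structure")
            k = n
        return float(doses[k - 1] if hottest else doses[n - k])

    out: Dict[str, float] = {}
    for m in metrics:
        if m == "mean":
            out[m] = float(doses.mean())
        elif m.startswith("V"):
            frac = float(m[1:]) / 100.0
            out[m] = float(100.0 * (doses >= frac * prescription_gy).sum() / n)
        elif m.startswith("Dmin_") and m.endswith("cc"):
            out[m] = d_cc(float(m[5:-2]), hottest=False)
        elif m.startswith("Dmax_") and m.endswith("cc"):
            out[m] = d_cc(float(m[5:-2]), hottest=True)
        elif m.endswith("cc"):
            out[m] = d_cc(float(m[1:-2]), hottest=True)
        elif m.startswith("D"):
            out[m] = d_percent(float(m[1:]))
        else:
            raise ValueError(f"unknown DVH metric {m!r}")
    return DVHRecord(name, out, flags)


# ---------------------------------------------------------------------------
# Plans


@dataclass
class PlanResult:
    plan_type: str  # P_WH | P_RF | P_WF
    modality: str  # brachy | ebrt
    prescription_gy: float
    boost_gy: Optional[float]
    dose: VolumeGrid
    table: pd.DataFrame  # columns: structure, metric, value
    seeds: Optional[SeedConfiguration] = None

    @property
    def n_seeds(self) -> int:
        return self.seeds.n_seeds if self.seeds is not None else 0

    @property
    def n_needles(self) -> int:
        return self.seeds.n_needles if self.seeds is not None else 0

    def metric(self, structure: str, name: str) -> float:
        sel = self.table[(self.table.structure == structure) & (self.table.metric == name)]
        if sel.empty:
            raise SchemaError(f"no metric {name!r} for structure {structure!r}")
        return float(sel.value.iloc[0])


def _dvh_table(dose: VolumeGrid, structures: StructureSet, targets: Dict[str, np.ndarray],
               prescription: float, schema: Sequence[str], metrics: Sequence[str]) -> pd.DataFrame:
    rows = []
    for name in schema:
        mask = targets.get(name)
        if mask is None:
            if name not in structures:
                raise SchemaError(f"missing structure {name!r}")
            mask = structures[name]
        if not mask.any():
            continue
        rec = dvh_metrics(dose, mask, prescription, metrics, name)
        for m, v in rec.metrics.items():
            rows.append({"structure": name, "metric": m, "value": v,
                         "flag": ";".join(rec.flags)})
    return pd.DataFrame(rows)


def build_plan(plan_type: str, targets: Optional[TargetVolumes], structures: StructureSet,
               modality: str = "brachy",
               prescription_gy: Optional[float] = None,
               boost_gy: Optional[float] = None) -> PlanResult:
    """Generate one plan and its DVH table.

    Brachytherapy plans default to the 145 Gy prescription (focal boost at
    150 %); the EBRT surrogate defaults to 79.2 Gy whole gland and a
    boosted 85.8 Gy. Focal plan types require a non-empty GTV.
    """
    if plan_type not in ("P_WH", "P_RF", "P_WF"):
        raise ValueError(f"unknown plan type {plan_type!r}")
    if modality not in ("brachy", "ebrt"):
        raise ValueError(f"unknown modality {modality!r}")
    if "prostate" not in structures:
        raise SchemaError("missing structure 'prostate'")
    prostate = structures["prostate"]
    geometry = structures.reference
    if plan_type in ("P_RF", "P_WF"):
        if targets is None or not targets.gtv.any():
            raise SchemaError(f"{plan_type} requires a non-empty GTV")

    if modality == "brachy":
        rx = BRACHY_PRESCRIPTION_GY if prescription_gy is None else prescription_gy
        boost = BRACHY_BOOST_GY if boost_gy is None else boost_gy
        exclusions = [structures["urethra"]] if "urethra" in structures else []
        urethra = structures["urethra"] if "urethra" in structures else None
        # whole-gland implants keep needles just off the urethra; focal
        # plans enforce a wider urethral-sparing standoff by design
        if plan_type == "P_WH":
            seeds = place_seeds(prostate, rx, geometry, avoid=urethra,
                                avoid_margin_mm=2.0)
            plan_targets = {"ptv": prostate}
        elif plan_type == "P_RF":
            # the focal plan escalates dose to the PTV (150 % of prescription)
            ptv = targets.ptv
            seeds = place_seeds(ptv, boost, geometry, avoid=urethra)
            plan_targets = {"ptv": ptv}
        else:  # P_WF: whole gland + boost to GTV + 2 mm
            seeds = place_seeds(prostate, rx, geometry, avoid=urethra,
                                avoid_margin_mm=2.0)
            boost_tgt = expand_margin(targets.gtv, BOOST_MARGIN_MM, prostate,
                                      exclusions, geometry.spacing)
            base = compute_seed_dose(seeds, geometry,
                                     points=np.argwhere(boost_tgt) * np.asarray(geometry.spacing)
                                     + np.asarray(geometry.origin))
            if np.percentile(base, 10) < boost:
                extra = place_seeds(boost_tgt, boost - np.percentile(base, 10), geometry,
                                    avoid=urethra)
                seeds = SeedConfiguration(
                    np.vstack([seeds.positions, extra.positions]),
                    np.concatenate([seeds.strengths, extra.strengths]),
                    np.concatenate([seeds.needle_ids,
                                    extra.needle_ids + seeds.n_needles]))
            plan_targets = {"ptv": prostate}
        dose = compute_seed_dose(seeds, geometry)
        table = _dvh_table(dose, structures, plan_targets, rx,
                           BRACHY_STRUCTURES, BRACHY_METRICS)
        return PlanResult(plan_type, modality, rx, boost if plan_type == "P_WF" else None,
                          dose, table, seeds)

    # EBRT surrogate (on the CT grid)
    rx = EBRT_PRESCRIPTION_GY if prescription_gy is None else prescription_gy
    boost = EBRT_BOOST_GY if boost_gy is None else boost_gy
    wg_ptv = ndimage.binary_dilation(prostate, iterations=1, structure=np.ones((3, 3, 1), bool))
    if plan_type == "P_WH":
        dose = ebrt_dose(wg_ptv, geometry, rx)
        plan_targets = {"ptv": wg_ptv}
    elif plan_type == "P_RF":
        boost_ptv = expand_margin(targets.gtv, FOCAL_MARGIN_MM, prostate, [], geometry.spacing)
        dose = ebrt_dose(boost_ptv, geometry, boost)
        plan_targets = {"ptv": boost_ptv}
    else:
        base = ebrt_dose(wg_ptv, geometry, rx)
        boost_ptv = expand_margin(targets.gtv, BOOST_MARGIN_MM, prostate, [], geometry.spacing)
        d95_base = np.percentile(base.values[boost_ptv], 5)
        extra = ebrt_dose(boost_ptv, geometry, max(boost - d95_base, 0.0) or 1e-9)
        dose = base.with_values(base.values + extra.values)
        plan_targets = {"ptv": wg_ptv}
    table = _dvh_table(dose, structures, plan_targets, rx, EBRT_STRUCTURES, EBRT_METRICS)
    return PlanResult(plan_type, "ebrt", rx, boost if plan_type != "P_WH" else None,
                      dose, table)


def compare_plans(a: PlanResult, b: PlanResult) -> pd.DataFrame:
    """Per-metric differences a - b with labels preserved."""
    ka = a.table.set_index(["structure", "metric"]).value
    kb = b.table.set_index(["structure", "metric"]).value
    if not ka.index.equals(kb.index):
        raise SchemaError("plans have different structure/metric schemas")
    delta = (ka - kb).reset_index()
    delta.columns = ["structure", "metric", "delta"]
    return delta
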