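"""End-to-end orchestration: detect -> transfer -> plan on phantom cohorts.

The experiment layout mirrors a two-institution design: a training cohort
and a disjoint test cohort of synthetic cases (split by case id, never by
voxel). ``run_all`` executes the three stages and writes every report as a
plain-text table into a run directory, so identical configs and seeds
reproduce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import classify, plan as planmod, radiomics, register, standardize
from .classify import ProbabilityMap
from .core import StructureSet, VolumeGrid
from .phantom import PhantomCase, PhantomSpec, make_phantom_case
from .register import RegistrationConfig
from .transforms import CompositeTransform

log = logging.getLogger(__name__)


class LeakageError(ValueError):
    """Raised when train and test case ids overlap."""


@dataclass
class RunConfig:
    """All knobs of one end-to-end phantom experiment."""

    seed: int = 7
    n_train: int = 5
    n_test: int = 3
    n_register: int = 2  # test cases taken through registration + EBRT
    lesion_contrast: float = 0.4
    noise_fraction: float = 0.10  # of the PZ background, per sequence
    deformation_amplitude: float = 6.0
    mrmr_k: int = classify.DEFAULT_K
    mi_bins: int = classify.DEFAULT_MI_BINS
    qda_regularization: float = classify.DEFAULT_REGULARIZATION
    smoothing_sigma_mm: float = classify.DEFAULT_SMOOTH_SIGMA_MM
    threshold: float = 0.5
    focal_margin_mm: float = planmod.FOCAL_MARGIN_MM
    boost_margin_mm: float = planmod.BOOST_MARGIN_MM
    brachy_prescription_gy: float = planmod.BRACHY_PRESCRIPTION_GY
    brachy_boost_gy: float = planmod.BRACHY_BOOST_GY
    ebrt_prescription_gy: float = planmod.EBRT_PRESCRIPTION_GY
    ebrt_boost_gy: float = planmod.EBRT_BOOST_GY
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a plain-text ``key = value`` configuration file."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields or key == "registration":
                raise KeyError(f"unknown config key {key!r}")
            typ = float if "float" in str(fields[key]) else int
            kwargs[key] = typ(val)
        return cls(**kwargs)


def _case_specs(config: RunConfig) -> Tuple[List[Tuple[str, PhantomSpec]], List[Tuple[str, PhantomSpec]]]:
    """Per-case phantom specs; each case gets its own seed and T2w drift."""
    base = int(config.seed) % (2 ** 20)

    def spec_for(case_seed: int) -> PhantomSpec:
        rng = np.random.default_rng(case_seed)
        return PhantomSpec(
            seed=case_seed,
            lesion_contrast=config.lesion_contrast,
            noise_sd=400.0 * config.noise_fraction,
            adc_noise_sd=1400.0 * config.noise_fraction,
            deformation_amplitude=config.deformation_amplitude,
            drift_gain=float(rng.uniform(0.7, 1.4)),
            drift_offset=float(rng.uniform(0.0, 60.0)),
        )

    train = [(f"train{i:02d}", spec_for(base * 1009 + i)) for i in range(config.n_train)]
    test = [(f"test{i:02d}", spec_for(base * 1009 + 1000 + i)) for i in range(config.n_test)]
    train_ids = {c for c, _ in train}
    if train_ids & {c for c, _ in test}:
        raise LeakageError("train and test case ids overlap")
    return train, test


@dataclass
class DetectionReport:
    auc_table: pd.DataFrame  # case, auc
    selection: classify.SelectionResult
    model: classify.QDAModel
    probability_maps: Dict[str, ProbabilityMap]
    test_cases: Dict[str, PhantomCase]
    template: standardize.StandardizationMap


def _standardized_t2w(case_t2w: VolumeGrid, prostate: np.ndarray,
                      template: standardize.StandardizationMap) -> VolumeGrid:
    return standardize.apply_standardization(case_t2w, prostate, template)


def run_detect(config: RunConfig, adc_shift_mm: float = 0.0,
               t2w_only: bool = False) -> DetectionReport:
    """Standardize, extract, select, train on the training cohort; predict,
    smooth and score per-case AUC on the held-out cohort.

    ``adc_shift_mm`` artificially translates the ADC volume before
    extraction (sequence-misalignment experiments); ``t2w_only`` restricts
    the registry to the T2w half of the bank.
    """
    train_specs, test_specs = _case_specs(config)
    registry = radiomics.default_registry()
    if t2w_only:
        registry = [d for d in registry if d.sequence == "T2w"]

    train_cases = [(cid, *_mpmri_only(spec)) for cid, spec in train_specs]
    test_cases = {cid: make_phantom_case(spec) for cid, spec in test_specs}

    template = standardize.learn_template(
        [t2w for _, t2w, _, _ in train_cases],
        [st["prostate"] for _, _, _, st in train_cases])

    def features_for(t2w, adc, st):
        t2s = _standardized_t2w(t2w, st["prostate"], template)
        if adc_shift_mm:
            adc = _shift_volume(adc, adc_shift_mm)
        return radiomics.extract_features(t2s, adc, st["pz"], registry, st["lesion"])

    train_fm = radiomics.FeatureMatrix.concatenate(
        [features_for(t2w, adc, st) for _, t2w, adc, st in train_cases])
    selection = classify.mrmr_select(train_fm, config.mrmr_k, config.mi_bins)
    model = classify.train_qda(train_fm, selection, config.qda_regularization)

    rows, maps = [], {}
    for cid, case in test_cases.items():
        fm = features_for(case.t2w, case.adc, case.structures)
        pmap = classify.predict_probability(model, fm, case.t2w)
        pmap = classify.smooth_probability_map(pmap, config.smoothing_sigma_mm)
        _, auc = classify.roc_auc(pmap, case.structures["lesion"])
        rows.append({"case": cid, "auc": auc})
        maps[cid] = pmap
    return DetectionReport(pd.DataFrame(rows), selection, model, maps, test_cases, template)


def _mpmri_only(spec: PhantomSpec):
    from .phantom import generate_mpmri_phantom

    return generate_mpmri_phantom(spec)


def _shift_volume(vol: VolumeGrid, shift_mm: float) -> VolumeGrid:
    """Translate along the first in-plane axis (whole-voxel part exact)."""
    from scipy import ndimage as ndi

    shift_vox = shift_mm / vol.spacing[0]
    vals = ndi.shift(vol.values.astype(float), (shift_vox, 0, 0), order=1, mode="nearest")
    return vol.with_values(vals)


@dataclass
class TransferReport:
    dice_table: pd.DataFrame  # case, dice_rigid, dice_deformable
    ct_maps: Dict[str, ProbabilityMap]
    transforms: Dict[str, CompositeTransform]


def run_transfer(config: RunConfig, detection: DetectionReport) -> TransferReport:
    """Two-stage registration and probability-map transference per case."""
    rows, ct_maps, transforms = [], {}, {}
    case_ids = list(detection.test_cases)[: config.n_register]
    for cid in case_ids:
        case = detection.test_cases[cid]
        res = register.register_case(
            case.ct, case.t2w_large,
            case.structures_large["prostate"], case.structures_ct["prostate"],
            case.structures_ct["rectum"], config.registration)
        pmap = detection.probability_maps[cid]
        moved = register.transfer(pmap.grid, res.composite, case.ct, is_mask=False)
        mask_moved = register.transfer(
            VolumeGrid(pmap.mask.astype(np.uint8), pmap.grid.spacing, pmap.grid.origin, "MASK"),
            res.composite, case.ct, is_mask=True)
        ct_maps[cid] = ProbabilityMap(moved, mask_moved.values > 0.5)
        transforms[cid] = res.composite
        rows.append({"case": cid, "dice_rigid": res.dice_rigid,
                     "dice_deformable": res.dice_deformable})
    return TransferReport(pd.DataFrame(rows), ct_maps, transforms)


@dataclass
class PlanReport:
    brachy: Dict[str, planmod.PlanResult]
    ebrt: Dict[str, planmod.PlanResult]
    brachy_deltas: Dict[str, pd.DataFrame]
    ebrt_deltas: Dict[str, pd.DataFrame]


def run_plan(config: RunConfig, case: PhantomCase, pmap_mri: ProbabilityMap,
             pmap_ct: Optional[ProbabilityMap]) -> PlanReport:
    """Three brachytherapy plans on the MRI grid and, when a transferred
    probability map is available, three EBRT-surrogate plans on CT."""
    st = case.structures
    targets = planmod.make_targets(pmap_mri, st["prostate"], config.threshold,
                                   config.focal_margin_mm, [st["urethra"]])
    plan_types = ("P_WH", "P_RF", "P_WF") if targets.gtv.any() else ("P_WH",)
    if len(plan_types) == 1:
        log.warning("empty GTV: only the whole-gland plan is generated")
    brachy = {pt: planmod.build_plan(pt, targets, st, "brachy",
                                     config.brachy_prescription_gy, config.brachy_boost_gy)
              for pt in plan_types}
    ebrt, ebrt_deltas = {}, {}
    if pmap_ct is not None:
        stc = case.structures_ct
        targets_ct = planmod.make_targets(pmap_ct, stc["prostate"], config.threshold,
                                          config.focal_margin_mm)
        ct_types = ("P_WH", "P_RF", "P_WF") if targets_ct.gtv.any() else ("P_WH",)
        ebrt = {pt: planmod.build_plan(pt, targets_ct, stc, "ebrt",
                                       config.ebrt_prescription_gy, config.ebrt_boost_gy)
                for pt in ct_types}
        ebrt_deltas = {pt: planmod.compare_plans(ebrt[pt], ebrt["P_WH"])
                       for pt in ct_types if pt != "P_WH"}
    brachy_deltas = {pt: planmod.compare_plans(brachy[pt], brachy["P_WH"])
                     for pt in plan_types if pt != "P_WH"}
    return PlanReport(brachy, ebrt, brachy_deltas, ebrt_deltas)


# ---------------------------------------------------------------------------
# run-all


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: RunConfig, out_dir) -> Dict[str, object]:
    """Full detect -> transfer -> plan pipeline with a report directory.

    Returns the in-memory reports; writes deterministic text tables plus a
    manifest (config hash, registry hash, seed) under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    detection = run_detect(config)
    _write_table(detection.auc_table, out / "auc_per_case.tsv")
    _write_table(pd.DataFrame({"rank": range(1, len(detection.selection.names) + 1),
                               "feature": detection.selection.names,
                               "score": detection.selection.scores}),
                 out / "selected_features.tsv")
    detection.model.write(out / "qda_model.json")
    detection.template.write(out / "standardization_map.tsv")

    transfer_rep = run_transfer(config, detection)
    _write_table(transfer_rep.dice_table, out / "dice_per_case.tsv")

    plan_case = list(detection.test_cases)[0]
    planrep = run_plan(config, detection.test_cases[plan_case],
                       detection.probability_maps[plan_case],
                       transfer_rep.ct_maps.get(plan_case))
    for pt, pl in planrep.brachy.items():
        _write_table(pl.table, out / f"brachy_{pt}_dvh.tsv")
        if pl.seeds is not None:
            pl.seeds.write_table(out / f"brachy_{pt}_seeds.tsv")
    for pt, df in planrep.brachy_deltas.items():
        _write_table(df, out / f"brachy_delta_{pt}_minus_P_WH.tsv")
    for pt, pl in planrep.ebrt.items():
        _write_table(pl.table, out / f"ebrt_{pt}_dvh.tsv")
    for pt, df in planrep.ebrt_deltas.items():
        _write_table(df, out / f"ebrt_delta_{pt}_minus_P_WH.tsv")

    registry_hash = hashlib.sha256(
        "\n".join(d.name for d in radiomics.default_registry()).encode()).hexdigest()[:12]
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "registry_hash": registry_hash,
        "plan_case": plan_case,
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"detection": detection, "transfer": transfer_rep, "plans": planrep,
            "manifest": manifest}
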