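"""Landmark-based piecewise-linear T2w intensity standardization.

T2w MRI intensities drift across scanners and sessions; the classic remedy
maps a fixed set of histogram landmarks (percentiles of the intensities in a
region of interest) onto a template scale learned from a cohort, with linear
interpolation between landmarks. ADC maps are quantitative and are passed
through untouched by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .core import EmptyStructureError, VolumeGrid

DEFAULT_LANDMARKS = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)
STANDARD_RANGE = (0.0, 1000.0)


class DegenerateDistributionError(ValueError):
    """Raised when a region has (near-)constant intensity."""


@dataclass
class StandardizationMap:
    """Learned landmark mapping onto a fixed standard scale.

    ``template`` holds the landmark intensities on the standard scale
    (strictly increasing); ``per_scan`` the raw landmark intensities of each
    training scan, retained for auditability.
    """

    percentiles: Sequence[float]
    template: np.ndarray
    standard_range: tuple = STANDARD_RANGE
    per_scan: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        p = np.asarray(self.percentiles, dtype=float)
        if p.ndim != 1 or len(p) < 2 or np.any(np.diff(p) <= 0) or p[0] <= 0 or p[-1] >= 100:
            raise ValueError("landmark percentiles must be strictly increasing within (0, 100)")
        t = np.asarray(self.template, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("template landmark intensities must be strictly increasing")
        self.percentiles = tuple(p)
        self.template = t

    # -- plain-text serialization (percentile <TAB> template intensity) -----
    def write(self, path) -> None:
        lines = [f"# standard_range\t{self.standard_range[0]:.10g}\t{self.standard_range[1]:.10g}"]
        lines += [f"{p:.10g}\t{t:.10g}" for p, t in zip(self.percentiles, self.template)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "StandardizationMap":
        percentiles, template = [], []
        rng = STANDARD_RANGE
        for line in Path(path).read_text().splitlines():
            if line.startswith("# standard_range"):
                _, lo, hi = line.split("\t")
                rng = (float(lo), float(hi))
            elif line.strip():
                p, t = line.split("\t")
                percentiles.append(float(p))
                template.append(float(t))
        return cls(percentiles, np.asarray(template), rng)


def _region_values(volume: VolumeGrid, mask: Optional[np.ndarray]) -> np.ndarray:
    if mask is None:
        # whole-volume foreground via Otsu when no prostate mask is supplied
        thr = threshold_otsu(volume.values.astype(float))
        mask = volume.values > thr
    vals = volume.values[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise EmptyStructureError("standardization region mask is empty")
    return vals.astype(float)


def _scan_landmarks(vals: np.ndarray, percentiles) -> np.ndarray:
    lm = np.percentile(vals, percentiles)
    if lm[-1] - lm[0] < 1e-9:
        raise DegenerateDistributionError("region intensity distribution is (near-)constant")
    # percentile interpolation can produce ties on quantized data; nudge to
    # keep the knot sequence strictly increasing
    return np.maximum.accumulate(lm + np.arange(len(lm)) * 1e-9)


def learn_template(volumes: Sequence[VolumeGrid], region_masks: Optional[Sequence] = None,
                   percentiles: Sequence[float] = DEFAULT_LANDMARKS,
                   standard_range: tuple = STANDARD_RANGE) -> StandardizationMap:
    """Learn template landmarks as the cohort mean on the standard scale.

    Each scan's landmarks are linearly rescaled so its outer landmarks hit
    the standard range, then averaged across scans. A single volume acts as
    its own template.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one volume")
    if region_masks is None:
        region_masks = [None] * len(volumes)
    s_lo, s_hi = standard_range
    per_scan, rescaled = [], []
    for vol, mask in zip(volumes, region_masks):
        lm = _scan_landmarks(_region_values(vol, mask), percentiles)
        per_scan.append(lm)
        rescaled.append(s_lo + (lm - lm[0]) * (s_hi - s_lo) / (lm[-1] - lm[0]))
    template = np.mean(rescaled, axis=0)
    template = np.maximum.accumulate(template + np.arange(len(template)) * 1e-9)
    return StandardizationMap(percentiles, template, (float(s_lo), float(s_hi)), per_scan)


def apply_standardization(volume: VolumeGrid, region_mask: Optional[np.ndarray],
                          smap: StandardizationMap) -> VolumeGrid:
    """Map a scan onto the standard scale via its own region landmarks.

    The mapping is continuous piecewise-linear between the scan's landmark
    intensities and the template's; beyond the outer landmarks the adjacent
    segment's slope extrapolates, then values are clamped to the standard
    range. The mapping is monotone non-decreasing by construction.
    """
    vals = _region_values(volume, region_mask)
    scan_lm = _scan_landmarks(vals, smap.percentiles)
    out = _piecewise_map(volume.values.astype(float), scan_lm, smap.template, smap.standard_range)
    return volume.with_values(out)


def _piecewise_map(values, knots_in, knots_out, clamp_range):
    inner = np.interp(values, knots_in, knots_out)
    out = inner
    lo_slope = (knots_out[1] - knots_out[0]) / (knots_in[1] - knots_in[0])
    hi_slope = (knots_out[-1] - knots_out[-2]) / (knots_in[-1] - knots_in[-2])
    below = values < knots_in[0]
    above = values > knots_in[-1]
    out = np.where(below, knots_out[0] + (values - knots_in[0]) * lo_slope, out)
    out = np.where(above, knots_out[-1] + (values - knots_in[-1]) * hi_slope, out)
    return np.clip(out, clamp_range[0], clamp_range[1])
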