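"""Per-voxel radiomic feature extraction over the peripheral zone.

The bank holds 154 features per MRI sequence (T2w and ADC; 308 total):

=============  ====================================================  =====
family         members                                               count
=============  ====================================================  =====
intensity      raw (standardized) signal intensity                       1
firstorder     mean / std / median / range over windows 3, 5, 7         12
sobel          gx, gy, magnitude, and two diagonal gradients             5
haralick       13 co-occurrence statistics x windows {5,7} x
               offset distances {1,2}                                   52
gabor          6 orientations x 7 frequencies (response magnitude)      42
laws           21 separable 5x5 kernels x energy windows {5,7}          42
=============  ====================================================  =====

All windowed features are computed in-plane (2D per slice): prostate MRI
slice thickness is far coarser than the in-plane resolution. Convolutions
use reflective padding; window statistics truncate at slice edges.
Co-occurrence matrices are built per voxel from the window's own min-max
range quantized to 16 gray levels, which makes them robust to any affine
intensity remapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage, signal
from skimage.filters import gabor_kernel

from .core import GeometryError, VolumeGrid

SEQUENCES = ("T2w", "ADC")
FIRSTORDER_STATS = ("mean", "std", "median", "range")
FIRSTORDER_WINDOWS = (3, 5, 7)
SOBEL_NAMES = ("gx", "gy", "magnitude", "diag45", "diag135")
HARALICK_STATS = (
    "energy", "contrast", "correlation", "variance", "homogeneity",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "diff_variance", "diff_entropy", "imc1", "imc2",
)
HARALICK_WINDOWS = (5, 7)
HARALICK_DISTANCES = (1, 2)
HARALICK_GRAY_LEVELS = 16
GABOR_ORIENTATIONS_DEG = (0, 30, 60, 90, 120, 150)
GABOR_FREQUENCIES = (0.06, 0.09, 0.13, 0.18, 0.25, 0.33, 0.45)
LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}
# 20 ordered pairs of distinct vectors plus the ripple-ripple kernel: every
# zero-sum separable 5x5 mask family member, including the three named in
# the selected-feature panel (R5E5, L5W5, W5L5).
LAWS_PAIRS = tuple(
    a + b for a in ("L5", "E5", "S5", "W5", "R5") for b in ("L5", "E5", "S5", "W5", "R5")
    if a != b
) + ("R5R5",)
LAWS_WINDOWS = (5, 7)


@dataclass(frozen=True)
class FeatureDescriptor:
    """One named feature: family, source sequence and parameters."""

    name: str
    sequence: str
    family: str
    window: Optional[int] = None
    params: Tuple = ()

    def __post_init__(self):
        if self.window is not None and (self.window < 3 or self.window % 2 == 0):
            raise ValueError(f"{self.name}: window must be odd and >= 3")


def default_registry() -> List[FeatureDescriptor]:
    """The fixed 308-entry feature registry (154 per sequence)."""
    reg: List[FeatureDescriptor] = []
    for seq in SEQUENCES:
        reg.append(FeatureDescriptor(f"{seq}.intensity", seq, "intensity"))
        for stat in FIRSTORDER_STATS:
            for w in FIRSTORDER_WINDOWS:
                reg.append(FeatureDescriptor(f"{seq}.firstorder.{stat}.w{w}", seq, "firstorder", w, (stat,)))
        for comp in SOBEL_NAMES:
            reg.append(FeatureDescriptor(f"{seq}.sobel.{comp}", seq, "sobel", None, (comp,)))
        for stat in HARALICK_STATS:
            for w in HARALICK_WINDOWS:
                for d in HARALICK_DISTANCES:
                    reg.append(FeatureDescriptor(
                        f"{seq}.haralick.{stat}.w{w}.d{d}", seq, "haralick", w, (stat, d)))
        for theta in GABOR_ORIENTATIONS_DEG:
            for freq in GABOR_FREQUENCIES:
                reg.append(FeatureDescriptor(
                    f"{seq}.gabor.t{theta}.f{freq:g}", seq, "gabor", None, (theta, freq)))
        for pair in LAWS_PAIRS:
            for w in LAWS_WINDOWS:
                reg.append(FeatureDescriptor(f"{seq}.laws.{pair}.w{w}", seq, "laws", w, (pair,)))
    names = [d.name for d in reg]
    assert len(names) == len(set(names)) == 308
    return reg


@dataclass
class FeatureMatrix:
    """Per-voxel feature vectors with voxel indices and optional labels."""

    values: np.ndarray  # (n_voxels, n_features)
    columns: List[str]
    voxels: np.ndarray  # (n_voxels, 3) int indices into the source grid
    labels: Optional[np.ndarray] = None  # bool, True = malignant

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None and len(self.labels) != len(self.values):
            raise ValueError("label length mismatch")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.columns.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], list(names), self.voxels, self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df.insert(0, "k", self.voxels[:, 2])
        df.insert(0, "j", self.voxels[:, 1])
        df.insert(0, "i", self.voxels[:, 0])
        if self.labels is not None:
            df.insert(3, "label", np.where(self.labels, "malignant", "benign"))
        return df

    def write_table(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def concatenate(cls, parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        cols = parts[0].columns
        for p in parts:
            if p.columns != cols:
                raise ValueError("cannot concatenate matrices with different columns")
        labels = None
        if all(p.labels is not None for p in parts):
            labels = np.concatenate([p.labels for p in parts])
        return cls(np.vstack([p.values for p in parts]), list(cols),
                   np.vstack([p.voxels for p in parts]), labels)


# ---------------------------------------------------------------------------
# Local first-order statistics (truncated in-plane windows)


def local_statistics(volume: VolumeGrid, mask: Optional[np.ndarray], window: int) -> Dict[str, np.ndarray]:
    """Windowed mean/std/median/range maps, one value per voxel.

    Edge windows are truncated to the slice. Returns full-volume maps; the
    mask only limits which slices are processed (maps are zero elsewhere).
    """
    _check_window(volume, window)
    maps = {s: np.zeros(volume.shape) for s in FIRSTORDER_STATS}
    slices = _active_slices(volume, mask)
    for k in slices:
        sl = volume.values[:, :, k].astype(float)
        win = _window_stack(sl, window)
        maps["mean"][:, :, k] = np.nanmean(win, axis=-1)
        maps["std"][:, :, k] = np.nanstd(win, axis=-1)
        maps["median"][:, :, k] = np.nanmedian(win, axis=-1)
        maps["range"][:, :, k] = np.nanmax(win, axis=-1) - np.nanmin(win, axis=-1)
    return maps


def _check_window(volume: VolumeGrid, window: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > min(volume.shape[0], volume.shape[1]):
        raise ValueError(f"window {window} exceeds the slice dimensions {volume.shape[:2]}")


def _active_slices(volume: VolumeGrid, mask: Optional[np.ndarray]):
    if mask is None:
        return range(volume.shape[2])
    return [k for k in range(volume.shape[2]) if mask[:, :, k].any()]


def _window_stack(sl: np.ndarray, window: int) -> np.ndarray:
    """(nx, ny, window*window) view with NaN outside the slice (truncation)."""
    h = window // 2
    padded = np.pad(sl, h, mode="constant", constant_values=np.nan)
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    return view.reshape(sl.shape + (window * window,))


# ---------------------------------------------------------------------------
# Sobel gradients

_SOBEL_X = np.array([[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]])  # d/dx (axis 0)
_SOBEL_Y = _SOBEL_X.T
_SOBEL_D45 = np.array([[0.0, 1.0, 2.0], [-1.0, 0.0, 1.0], [-2.0, -1.0, 0.0]])
_SOBEL_D135 = np.array([[-2.0, -1.0, 0.0], [-1.0, 0.0, 1.0], [0.0, 1.0, 2.0]])


def sobel_gradients(volume: VolumeGrid, mask: Optional[np.ndarray] = None) -> Dict[str, np.ndarray]:
    """Per-slice 3x3 Sobel gradient maps (unnormalized kernels).

    Returns gx, gy (in-plane axes 0 and 1), gradient magnitude, and the two
    diagonal-kernel responses.
    """
    if volume.shape[0] < 3 or volume.shape[1] < 3:
        raise GeometryError("slice dimensions must be >= 3 for Sobel gradients")
    maps = {s: np.zeros(volume.shape) for s in SOBEL_NAMES}
    for k in _active_slices(volume, mask):
        sl = volume.values[:, :, k].astype(float)
        gx = ndimage.correlate(sl, _SOBEL_X, mode="reflect")
        gy = ndimage.correlate(sl, _SOBEL_Y, mode="reflect")
        maps["gx"][:, :, k] = gx
        maps["gy"][:, :, k] = gy
        maps["magnitude"][:, :, k] = np.hypot(gx, gy)
        maps["diag45"][:, :, k] = ndimage.correlate(sl, _SOBEL_D45, mode="reflect")
        maps["diag135"][:, :, k] = ndimage.correlate(sl, _SOBEL_D135, mode="reflect")
    return maps


# ---------------------------------------------------------------------------
# Haralick co-occurrence statistics (numba-compiled per-voxel GLCM)


@njit(cache=True)
def _haralick_slice(sl, mask2d, half, levels, offsets, out):  # pragma: no cover - jitted
    nx, ny = sl.shape
    noff = offsets.shape[0]
    glcm = np.empty((levels, levels))
    for i in range(nx):
        for j in range(ny):
            if not mask2d[i, j]:
                continue
            i0 = max(0, i - half)
            i1 = min(nx, i + half + 1)
            j0 = max(0, j - half)
            j1 = min(ny, j + half + 1)
            vmin = sl[i0, j0]
            vmax = sl[i0, j0]
            for a in range(i0, i1):
                for b in range(j0, j1):
                    v = sl[a, b]
                    if v < vmin:
                        vmin = v
                    if v > vmax:
                        vmax = v
            span = vmax - vmin
            glcm[:, :] = 0.0
            total = 0.0
            for a in range(i0, i1):
                for b in range(j0, j1):
                    if span > 1e-12:
                        qa = int((sl[a, b] - vmin) / span * levels)
                        if qa >= levels:
                            qa = levels - 1
                    else:
                        qa = 0
                    for o in range(noff):
                        a2 = a + offsets[o, 0]
                        b2 = b + offsets[o, 1]
                        if a2 < i0 or a2 >= i1 or b2 < j0 or b2 >= j1:
                            continue
                        if span > 1e-12:
                            qb = int((sl[a2, b2] - vmin) / span * levels)
                            if qb >= levels:
                                qb = levels - 1
                        else:
                            qb = 0
                        glcm[qa, qb] += 1.0
                        glcm[qb, qa] += 1.0
                        total += 2.0
            if total == 0.0:
                for s in range(13):
                    out[s, i, j] = 0.0
                continue
            for a in range(levels):
                for b in range(levels):
                    glcm[a, b] /= total
            _glcm_statistics(glcm, levels, out, i, j)


@njit(cache=True)
def _glcm_statistics(p, levels, out, i, j):  # pragma: no cover - jitted
    px = np.zeros(levels)
    py = np.zeros(levels)
    psum = np.zeros(2 * levels - 1)
    pdiff = np.zeros(levels)
    energy = 0.0
    contrast = 0.0
    homog = 0.0
    entropy = 0.0
    cross = 0.0
    for a in range(levels):
        for b in range(levels):
            v = p[a, b]
            px[a] += v
            py[b] += v
            psum[a + b] += v
            pdiff[abs(a - b)] += v
            energy += v * v
            contrast += (a - b) * (a - b) * v
            homog += v / (1.0 + (a - b) * (a - b))
            cross += a * b * v
            if v > 1e-15:
                entropy -= v * np.log(v)
    mx = 0.0
    my = 0.0
    for a in range(levels):
        mx += a * px[a]
        my += a * py[a]
    vx = 0.0
    vy = 0.0
    hx = 0.0
    hy = 0.0
    for a in range(levels):
        vx += (a - mx) * (a - mx) * px[a]
        vy += (a - my) * (a - my) * py[a]
        if px[a] > 1e-15:
            hx -= px[a] * np.log(px[a])
        if py[a] > 1e-15:
            hy -= py[a] * np.log(py[a])
    sx = np.sqrt(vx)
    sy = np.sqrt(vy)
    if sx * sy > 1e-12:
        corr = (cross - mx * my) / (sx * sy)
    else:
        corr = 0.0
    sum_avg = 0.0
    sum_ent = 0.0
    for k in range(2 * levels - 1):
        sum_avg += k * psum[k]
        if psum[k] > 1e-15:
            sum_ent -= psum[k] * np.log(psum[k])
    sum_var = 0.0
    for k in range(2 * levels - 1):
        sum_var += (k - sum_avg) * (k - sum_avg) * psum[k]
    diff_avg = 0.0
    diff_ent = 0.0
    for k in range(levels):
        diff_avg += k * pdiff[k]
        if pdiff[k] > 1e-15:
            diff_ent -= pdiff[k] * np.log(pdiff[k])
    diff_var = 0.0
    for k in range(levels):
        diff_var += (k - diff_avg) * (k - diff_avg) * pdiff[k]
    hxy1 = 0.0
    hxy2 = 0.0
    for a in range(levels):
        for b in range(levels):
            q = px[a] * py[b]
            if q > 1e-15:
                hxy2 -= q * np.log(q)
                if p[a, b] > 1e-15:
                    hxy1 -= p[a, b] * np.log(q)
    hmax = hx if hx > hy else hy
    imc1 = (entropy - hxy1) / hmax if hmax > 1e-12 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = np.sqrt(arg) if arg > 0.0 else 0.0
    out[0, i, j] = energy
    out[1, i, j] = contrast
    out[2, i, j] = corr
    out[3, i, j] = vx
    out[4, i, j] = homog
    out[5, i, j] = sum_avg
    out[6, i, j] = sum_var
    out[7, i, j] = sum_ent
    out[8, i, j] = entropy
    out[9, i, j] = diff_var
    out[10, i, j] = diff_ent
    out[11, i, j] = imc1
    out[12, i, j] = imc2


def default_offsets(distance: int) -> List[Tuple[int, int]]:
    """The four standard in-plane directions at the given distance."""
    d = int(distance)
    return [(d, 0), (0, d), (d, d), (d, -d)]


def haralick_features(volume: VolumeGrid, mask: Optional[np.ndarray], window: int,
                      gray_levels: int = HARALICK_GRAY_LEVELS,
                      offsets: Optional[Sequence[Tuple[int, int]]] = None,
                      ) -> Dict[str, np.ndarray]:
    """13 Haralick statistics from per-voxel local co-occurrence matrices.

    Per voxel, the window's intensities are quantized to ``gray_levels``
    over the window's own min-max range; a symmetric co-occurrence matrix is
    accumulated over all offsets (pairs fully inside the window), normalized
    to sum 1, and summarized. A constant window concentrates all mass in one
    cell (energy 1, entropy 0, contrast 0); correlation is set to 0 when a
    marginal is degenerate.
    """
    if gray_levels < 2:
        raise ValueError("gray levels must be >= 2")
    _check_window(volume, window)
    if offsets is None:
        offsets = default_offsets(1)
    off = np.asarray(offsets, dtype=np.int64)
    if mask is None:
        mask = np.ones(volume.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    maps = {s: np.zeros(volume.shape) for s in HARALICK_STATS}
    out = np.zeros((13,) + volume.shape[:2])
    for k in _active_slices(volume, mask):
        out[:] = 0.0
        _haralick_slice(volume.values[:, :, k].astype(np.float64),
                        mask[:, :, k], window // 2, int(gray_levels), off, out)
        for s, name in enumerate(HARALICK_STATS):
            maps[name][:, :, k] = out[s]
    return maps


# ---------------------------------------------------------------------------
# Gabor filter bank


def _gabor_kernels(orientations_deg=GABOR_ORIENTATIONS_DEG,
                   frequencies=GABOR_FREQUENCIES) -> Dict[Tuple[float, float], np.ndarray]:
    """Complex Gabor kernels with the even (real) part made zero-DC.

    The envelope width tracks the wavelength but is capped so kernels stay
    local relative to the small prostate fields of view.
    """
    kernels = {}
    for theta in orientations_deg:
        for freq in frequencies:
            sigma = min(0.56 / freq, 3.5)
            # orientation measured against in-plane axis 0 (x); skimage's
            # theta runs against its row axis, hence the complement
            k = gabor_kernel(freq, theta=np.deg2rad(90.0 - theta), sigma_x=sigma, sigma_y=sigma)
            k = k - k.real.mean()  # zero DC on the even part
            kernels[(theta, freq)] = k
    return kernels


def _conv2_reflect(sl: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same' convolution with reflective padding (FFT-based)."""
    hx = kernel.shape[0] // 2
    hy = kernel.shape[1] // 2
    px = min(hx, sl.shape[0] - 1)
    py = min(hy, sl.shape[1] - 1)
    padded = np.pad(sl, ((px, px), (py, py)), mode="reflect")
    full = signal.fftconvolve(padded, kernel, mode="same")
    return full[px:px + sl.shape[0], py:py + sl.shape[1]]


def gabor_bank(volume: VolumeGrid, mask: Optional[np.ndarray] = None,
               orientations_deg=GABOR_ORIENTATIONS_DEG,
               frequencies=GABOR_FREQUENCIES) -> Dict[Tuple[float, float], np.ndarray]:
    """Response-magnitude maps, one per (orientation, frequency)."""
    for f in frequencies:
        if not 0.0 < f <= 0.5:
            raise ValueError(f"frequency {f} outside (0, 0.5] cycles/voxel")
    kernels = _gabor_kernels(orientations_deg, frequencies)
    maps = {key: np.zeros(volume.shape) for key in kernels}
    for k in _active_slices(volume, mask):
        sl = volume.values[:, :, k].astype(float)
        for key, kern in kernels.items():
            re = _conv2_reflect(sl, kern.real)
            im = _conv2_reflect(sl, kern.imag)
            maps[key][:, :, k] = np.hypot(re, im)
    return maps


# ---------------------------------------------------------------------------
# Laws texture energy


def laws_energy(volume: VolumeGrid, kernel_pair: str, energy_window: int,
                mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Windowed mean absolute response to a separable 5x5 Laws mask.

    The 2D mask is the outer product of the two named 1D vectors (first
    along in-plane axis 0); the energy is the truncated-window mean of the
    absolute filter response.
    """
    if len(kernel_pair) != 4 or kernel_pair[:2] not in LAWS_VECTORS or kernel_pair[2:] not in LAWS_VECTORS:
        raise ValueError(f"unknown Laws kernel pair {kernel_pair!r}")
    _check_window(volume, energy_window)
    kern = np.outer(LAWS_VECTORS[kernel_pair[:2]], LAWS_VECTORS[kernel_pair[2:]])
    out = np.zeros(volume.shape)
    for k in _active_slices(volume, mask):
        sl = volume.values[:, :, k].astype(float)
        resp = np.abs(ndimage.correlate(sl, kern, mode="reflect"))
        out[:, :, k] = _truncated_window_mean(resp, energy_window)
    return out


def _truncated_window_mean(sl: np.ndarray, window: int) -> np.ndarray:
    kern = np.ones((window, window))
    total = ndimage.correlate(sl, kern, mode="constant", cval=0.0)
    count = ndimage.correlate(np.ones_like(sl), kern, mode="constant", cval=0.0)
    return total / count


# ---------------------------------------------------------------------------
# Full extraction


def extract_features(t2w: VolumeGrid, adc: VolumeGrid, mask: np.ndarray,
                     registry: Optional[List[FeatureDescriptor]] = None,
                     labels: Optional[np.ndarray] = None) -> FeatureMatrix:
    """Evaluate the registry at every in-mask voxel.

    ``t2w`` and ``adc`` must share a grid. ``labels`` is an optional binary
    volume (lesion mask) sampled at the same voxels.
    """
    if registry is None:
        registry = default_registry()
    if not t2w.same_geometry(adc):
        raise GeometryError("T2w and ADC must be on identical grids")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("extraction mask is empty")
    if mask.shape != t2w.shape:
        raise GeometryError("mask is not aligned with the volumes")
    idx = np.argwhere(mask)
    flat = (idx[:, 0], idx[:, 1], idx[:, 2])
    volumes = {"T2w": t2w, "ADC": adc}
    columns, data = [], []
    for seq in SEQUENCES:
        seq_desc = [d for d in registry if d.sequence == seq]
        if not seq_desc:
            continue
        vol = volumes[seq]
        maps = _family_maps(vol, mask, seq_desc)
        for d in seq_desc:
            columns.append(d.name)
            data.append(maps[d.name][flat])
    order = [d.name for d in registry]
    table = {c: v for c, v in zip(columns, data)}
    values = np.stack([table[c] for c in order], axis=1)
    lab = None if labels is None else np.asarray(labels, dtype=bool)[flat]
    return FeatureMatrix(values, order, idx, lab)


def _family_maps(vol: VolumeGrid, mask: np.ndarray, descriptors) -> Dict[str, np.ndarray]:
    maps: Dict[str, np.ndarray] = {}
    fams = {d.family for d in descriptors}
    by_name = {d.name: d for d in descriptors}
    if "intensity" in fams:
        for d in descriptors:
            if d.family == "intensity":
                maps[d.name] = vol.values.astype(float)
    if "firstorder" in fams:
        for w in sorted({d.window for d in descriptors if d.family == "firstorder"}):
            stats = local_statistics(vol, mask, w)
            for d in descriptors:
                if d.family == "firstorder" and d.window == w:
                    maps[d.name] = stats[d.params[0]]
    if "sobel" in fams:
        grads = sobel_gradients(vol, mask)
        for d in descriptors:
            if d.family == "sobel":
                maps[d.name] = grads[d.params[0]]
    if "haralick" in fams:
        configs = sorted({(d.window, d.params[1]) for d in descriptors if d.family == "haralick"})
        for w, dist in configs:
            feats = haralick_features(vol, mask, w, offsets=default_offsets(dist))
            for d in descriptors:
                if d.family == "haralick" and d.window == w and d.params[1] == dist:
                    maps[d.name] = feats[d.params[0]]
    if "gabor" in fams:
        gdesc = [d for d in descriptors if d.family == "gabor"]
        thetas = tuple(sorted({d.params[0] for d in gdesc}))
        freqs = tuple(sorted({d.params[1] for d in gdesc}))
        bank = gabor_bank(vol, mask, thetas, freqs)
        for d in gdesc:
            maps[d.name] = bank[(d.params[0], d.params[1])]
    if "laws" in fams:
        for d in descriptors:
            if d.family == "laws":
                maps[d.name] = laws_energy(vol, d.params[0], d.window, mask)
    return maps
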