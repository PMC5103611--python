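"""Synthetic paired mpMRI/CT pelvis phantoms with known ground truth.

The phantom emulates what the downstream stages consume from a clinical
prostate radiotherapy case: a small-FOV diagnostic T2w volume with an ADC
map, a large-FOV planning T2w volume, and a planning CT related to the MRI
by a known rigid transform plus a prostate-local deformation. Hypo-intense
lesions (on both T2w and ADC) are planted fully inside the peripheral zone,
which is where the detection stage operates; lesions additionally carry
reduced local texture so that co-occurrence and texture-energy features are
informative, not just raw intensity.

All anatomy is defined analytically in a single subject coordinate frame
(millimetres, origin at the prostate centre), so every mask on every grid is
exact — a voxel is a lesion voxel iff its centre lies in the generative
lesion sphere — and the CT is rendered by evaluating the same anatomy at the
ground-truth-transformed voxel positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import StructureSet, VolumeGrid
from .transforms import (
    CompositeTransform,
    DisplacementTransform,
    RigidTransform,
    jacobian_determinant,
)


class PlacementError(RuntimeError):
    """Raised when no feasible lesion position exists inside the PZ."""


class SupportError(ValueError):
    """Raised when the deformation support leaves the volume."""


@dataclass
class PhantomSpec:
    """Generation parameters; the defaults define the study conditions.

    Intensities are in arbitrary T2w units (peripheral-zone background 400),
    10^-6 mm^2/s for ADC (PZ background 1400) and HU for CT. ``noise_sd``
    and ``adc_noise_sd`` default to 10 % of the respective PZ background.
    ``lesion_contrast`` is the fractional intensity reduction of lesion vs PZ
    background on both sequences; ``texture_contrast`` is the fractional
    reduction of local texture amplitude inside lesions.
    """

    # small-FOV diagnostic grid (feature extraction happens here)
    shape: Tuple[int, int, int] = (64, 64, 16)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    # large-FOV planning grid (shared by the planning MRI and the CT)
    large_shape: Tuple[int, int, int] = (96, 96, 20)
    large_spacing: Tuple[float, float, float] = (1.5, 1.5, 3.0)
    prostate_semiaxes: Tuple[float, float, float] = (22.0, 18.0, 16.0)
    pz_thickness: float = 10.0
    lesion_count: int = 2
    lesion_radius: float = 4.0
    lesion_contrast: float = 0.4
    texture_amplitude: float = 40.0
    texture_contrast: float = 0.6
    noise_sd: float = 40.0
    adc_noise_sd: float = 140.0
    ct_noise_sd: float = 12.0
    drift_gain: float = 1.0
    drift_offset: float = 0.0
    rigid_translation: Tuple[float, float, float] = (4.0, 3.0, -2.0)
    rigid_angles_deg: Tuple[float, float, float] = (0.0, 0.0, 3.0)
    deformation_amplitude: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ValueError("lesion contrast must lie in (0, 1)")
        if self.deformation_amplitude >= min(self.prostate_semiaxes):
            raise ValueError("deformation amplitude must be below the prostate minor semi-axis")
        if self.drift_gain <= 0:
            raise ValueError("drift gain must be positive")


# tissue intensity tables (subject-frame structures -> per-modality values)
_T2W = {
    "background": 300.0, "fat": 550.0, "bone": 150.0, "bladder": 700.0, "rectum_wall": 330.0,
    "rectum_lumen": 50.0, "central_gland": 350.0, "pz": 400.0, "urethra": 320.0,
    "penile_bulb": 310.0, "air": 10.0,
}
_ADC = {
    "background": 900.0, "fat": 450.0, "bone": 400.0, "bladder": 2500.0, "rectum_wall": 950.0,
    "rectum_lumen": 300.0, "central_gland": 1100.0, "pz": 1400.0, "urethra": 1000.0,
    "penile_bulb": 950.0, "air": 300.0,
}
_CT = {
    "background": 30.0, "fat": -80.0, "bone": 600.0, "bladder": 15.0, "rectum_wall": 40.0,
    "rectum_lumen": -500.0, "central_gland": 45.0, "pz": 45.0, "urethra": 45.0,
    "penile_bulb": 35.0, "air": -1000.0,
}


def _ellipsoid(x, y, z, center, semiaxes) -> np.ndarray:
    cx, cy, cz = center
    a, b, c = semiaxes
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


@dataclass
class Anatomy:
    """Analytic subject-frame anatomy: structure membership at any point.

    The prostate is an ellipsoid at the origin; the peripheral zone is the
    posterior (+y) shell of thickness ``pz_thickness``; lesions are spheres
    fully inside the PZ. Rectum, bladder, urethra, penile bulb, femoral
    heads and a body outline complete the pelvis.
    """

    spec: PhantomSpec
    lesion_centers: List[np.ndarray] = field(default_factory=list)

    @property
    def inner_semiaxes(self) -> Tuple[float, float, float]:
        a, b, c = self.spec.prostate_semiaxes
        t = self.spec.pz_thickness
        return (max(a - t, 3.0), max(b - t, 3.0), max(c - t, 3.0))

    def masks_at(self, x, y, z) -> Dict[str, np.ndarray]:
        """Evaluate every structure mask at physical points (broadcastable)."""
        sp = self.spec
        prostate = _ellipsoid(x, y, z, (0, 0, 0), sp.prostate_semiaxes)
        inner = _ellipsoid(x, y, z, (0, 0, 0), self.inner_semiaxes)
        pz = prostate & ~inner & (y > 0)
        lesion = np.zeros_like(prostate)
        for ctr in self.lesion_centers:
            lesion |= ((x - ctr[0]) ** 2 + (y - ctr[1]) ** 2 + (z - ctr[2]) ** 2
                       <= sp.lesion_radius ** 2)
        urethra = (x ** 2 + y ** 2 <= 2.5 ** 2) & (np.abs(z) <= sp.prostate_semiaxes[2]) & prostate
        rect_r2 = (x - 0.0) ** 2 + (y - 32.0) ** 2
        rectum = (rect_r2 <= 10.0 ** 2) & (np.abs(z) <= 27.0)
        rectum_lumen = (rect_r2 <= 6.0 ** 2) & (np.abs(z) <= 27.0)
        bladder = _ellipsoid(x, y, z, (0.0, -12.0, 28.0), (26.0, 20.0, 14.0))
        bulb = _ellipsoid(x, y, z, (0.0, 8.0, -24.0), (8.0, 7.0, 6.0))
        fem = _ellipsoid(x, y, z, (-55.0, 5.0, 0.0), (14.0, 14.0, 16.0)) | _ellipsoid(
            x, y, z, (55.0, 5.0, 0.0), (14.0, 14.0, 16.0))
        body = ((x / 70.0) ** 2 + (y / 65.0) ** 2) <= 1.0
        # periprostatic/pelvic fat: the pocket holding the organs, minus them
        fat = _ellipsoid(x, y, z, (0.0, 6.0, 2.0), (42.0, 46.0, 38.0))
        for organ in (prostate, rectum, bladder, bulb, fem):
            fat &= ~organ
        # the prostate has priority over abutting soft-tissue structures
        for m in (rectum, rectum_lumen, bladder, bulb):
            m &= ~prostate
        return {
            "prostate": prostate, "pz": pz, "lesion": lesion & pz, "urethra": urethra,
            "rectum": rectum, "rectum_lumen": rectum_lumen, "bladder": bladder,
            "penile_bulb": bulb, "femoral_heads": fem, "body": body, "fat": fat,
        }

    def render(self, x, y, z, table: Dict[str, float], rng: np.random.Generator,
               noise_sd: float, texture: bool = False, poisson_like: bool = False) -> np.ndarray:
        """Noise-free tissue map + optional PZ texture + acquisition noise."""
        sp = self.spec
        masks = self.masks_at(x, y, z)
        img = np.full(x.shape, table["air"])
        img[masks["body"]] = table["background"]
        for name in ("fat:fat", "bone:femoral_heads", "bladder:bladder", "penile_bulb:penile_bulb",
                     "rectum_wall:rectum", "rectum_lumen:rectum_lumen",
                     "central_gland:prostate", "pz:pz", "urethra:urethra"):
            tissue, struct = name.split(":")
            img[masks[struct]] = table[tissue]
        if "pz" in table and table is not _CT:
            base = table["pz"]
            img[masks["lesion"]] = base * (1.0 - sp.lesion_contrast)
        if texture and sp.texture_amplitude > 0:
            tex = rng.standard_normal(x.shape)
            sigma_vox = [1.5 / s for s in self._spacing_of(x, y, z)]
            tex = ndimage.gaussian_filter(tex, sigma_vox)
            std = tex.std()
            if std > 0:
                tex /= std
            amp = np.zeros(x.shape)
            amp[masks["pz"]] = sp.texture_amplitude
            amp[masks["lesion"]] = sp.texture_amplitude * (1.0 - sp.texture_contrast)
            img = img + amp * tex
        if noise_sd > 0:
            if poisson_like:
                scale = np.sqrt(np.clip(img - table["air"], 0, None) / 1000.0)
                img = img + rng.standard_normal(x.shape) * noise_sd * scale
            else:
                img = img + rng.standard_normal(x.shape) * noise_sd
        return img

    @staticmethod
    def _spacing_of(x, y, z):
        def step(arr, axis):
            sl = [0] * arr.ndim
            sl[axis] = slice(0, 2)
            seg = arr[tuple(sl)].ravel()
            return abs(float(seg[1] - seg[0])) if seg.size > 1 else 1.0
        return (step(x, 0), step(y, 1), step(z, 2))


def _grid_coords(shape, spacing, center=(0.0, 0.0, 0.0)):
    """Physical coordinates of a grid centred on ``center``; returns origin too."""
    shape = tuple(shape)
    spacing = tuple(spacing)
    origin = tuple(center[a] - (shape[a] - 1) * spacing[a] / 2.0 for a in range(3))
    idx = np.indices(shape, dtype=float)
    x = origin[0] + idx[0] * spacing[0]
    y = origin[1] + idx[1] * spacing[1]
    z = origin[2] + idx[2] * spacing[2]
    return x, y, z, origin


def _place_lesions(anatomy: Anatomy, rng: np.random.Generator, max_tries: int = 500) -> None:
    """Sample lesion centres fully inside the PZ (bounded rejection)."""
    sp = anatomy.spec
    r = sp.lesion_radius
    a, b, c = sp.prostate_semiaxes
    ia, ib, ic = anatomy.inner_semiaxes
    # candidate centres on a fine subject-frame lattice restricted to the PZ
    xs = np.arange(-a, a + 0.5, 1.0)
    ys = np.arange(0.0, b + 0.5, 1.0)
    zs = np.arange(-c, c + 0.5, 1.0)
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")
    inside_outer = _ellipsoid(x, y, z, (0, 0, 0), (a - r, b - r, c - r))
    outside_inner = ~_ellipsoid(x, y, z, (0, 0, 0), (ia + r, ib + r, ic + r))
    feasible = inside_outer & outside_inner & (y >= r)
    cand = np.stack([x[feasible], y[feasible], z[feasible]], axis=1)
    if cand.size == 0:
        raise PlacementError(
            f"no feasible centre for lesion radius {r} mm inside a {sp.pz_thickness} mm PZ shell")
    centers: List[np.ndarray] = []
    tries = 0
    while len(centers) < sp.lesion_count:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {sp.lesion_count} non-overlapping lesions in {max_tries} tries")
        tries += 1
        ctr = cand[rng.integers(len(cand))]
        if all(np.linalg.norm(ctr - c0) >= 2 * r + 3.0 for c0 in centers):
            centers.append(ctr)
    anatomy.lesion_centers = centers


def _structure_set(anatomy: Anatomy, ref: VolumeGrid, names) -> StructureSet:
    x, y, z = ref.physical_grid()
    masks = anatomy.masks_at(x, y, z)
    return StructureSet(reference=ref, structures={n: masks[n] for n in names})


_MRI_STRUCTS = ("prostate", "pz", "lesion", "urethra", "rectum", "bladder")
_CT_STRUCTS = ("prostate", "pz", "lesion", "urethra", "rectum", "bladder",
               "penile_bulb", "femoral_heads")


def generate_mpmri_phantom(spec: PhantomSpec):
    """Generate the small-FOV T2w + ADC pair with its structure set.

    Returns ``(t2w, adc, structures)``; the structure set carries the
    sampled :class:`Anatomy` as ``structures.anatomy`` so that the CT stage
    can render the same subject. Identical specs (and seeds) give identical
    volumes.
    """
    rng = np.random.default_rng(spec.seed)
    anatomy = Anatomy(spec)
    _place_lesions(anatomy, rng)
    x, y, z, origin = _grid_coords(spec.shape, spec.spacing)
    t2_vals = anatomy.render(x, y, z, _T2W, rng, spec.noise_sd, texture=True)
    adc_vals = anatomy.render(x, y, z, _ADC, rng, spec.adc_noise_sd, texture=True)
    t2w = VolumeGrid(t2_vals, spec.spacing, origin, "T2w_small_FOV")
    adc = VolumeGrid(adc_vals, spec.spacing, origin, "ADC")
    if spec.drift_gain != 1.0 or spec.drift_offset != 0.0:
        t2w = apply_intensity_drift(t2w, spec.drift_gain, spec.drift_offset)
    structures = _structure_set(anatomy, t2w, _MRI_STRUCTS)
    structures.anatomy = anatomy
    return t2w, adc, structures


def generate_large_fov(spec: PhantomSpec, anatomy: Anatomy):
    """Render the large-FOV planning T2w of the same subject."""
    rng = np.random.default_rng(spec.seed + 1_000_003)
    x, y, z, origin = _grid_coords(spec.large_shape, spec.large_spacing)
    vals = anatomy.render(x, y, z, _T2W, rng, spec.noise_sd, texture=True)
    t2w = VolumeGrid(vals, spec.large_spacing, origin, "T2w_large_FOV")
    return t2w, _structure_set(anatomy, t2w, _MRI_STRUCTS)


def make_deformation_field(spec: PhantomSpec, geometry: VolumeGrid,
                           prostate_center_fixed, rng: np.random.Generator,
                           amplitude: Optional[float] = None) -> DisplacementTransform:
    """Smooth prostate-local deformation: a sum of Gaussian bumps.

    Bump centres sit inside the fixed-space prostate; the field is windowed
    to vanish exactly beyond the prostate+rectum neighbourhood so the
    region-restriction contract of the registration stage has a ground
    truth. The field is rescaled so its maximum magnitude equals
    ``amplitude`` (default ``spec.deformation_amplitude``).
    """
    amp = spec.deformation_amplitude if amplitude is None else amplitude
    x, y, z = geometry.physical_grid()
    ctr = np.asarray(prostate_center_fixed, dtype=float)
    fld = np.zeros(geometry.shape + (3,))
    if amp > 0:
        for _ in range(3):
            bump_ctr = ctr + rng.uniform(-8.0, 8.0, size=3)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            sigma = rng.uniform(8.0, 12.0)
            w = np.exp(-(((x - bump_ctr[0]) ** 2 + (y - bump_ctr[1]) ** 2
                          + (z - bump_ctr[2]) ** 2) / (2 * sigma ** 2)))
            fld += w[..., None] * direction
        # smooth cosine window: 1 within r0 of the prostate centre, 0 past r0+12
        r0 = max(spec.prostate_semiaxes) + 10.0
        dist = np.sqrt((x - ctr[0]) ** 2 + (y - ctr[1]) ** 2 + (z - ctr[2]) ** 2)
        win = np.clip((dist - r0) / 12.0, 0.0, 1.0)
        window = 0.5 * (1.0 + np.cos(np.pi * win))
        window[dist >= r0 + 12.0] = 0.0
        fld *= window[..., None]
        mag = np.linalg.norm(fld, axis=-1).max()
        if mag > 0:
            fld *= amp / mag
        support = dist < r0 + 12.0
        lo = geometry.voxel_to_physical((0, 0, 0))
        hi = geometry.voxel_to_physical(np.asarray(geometry.shape) - 1)
        if np.any(ctr - (r0 + 12.0) < lo - 25.0) or np.any(ctr + r0 + 12.0 > hi + 25.0):
            raise SupportError("deformation support extends far outside the volume")
    else:
        support = np.zeros(geometry.shape, dtype=bool)
    return DisplacementTransform(fld, geometry.spacing, geometry.origin, support=support)


def sample_ground_truth_transform(spec: PhantomSpec, rng: Optional[np.random.Generator] = None):
    """Draw the ground-truth (rigid, deformation) pair for the CT stage."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 7_777)
    rigid = RigidTransform.from_params(spec.rigid_angles_deg, spec.rigid_translation)
    x, y, z, origin = _grid_coords(spec.large_shape, spec.large_spacing)
    geometry = VolumeGrid(np.zeros(spec.large_shape), spec.large_spacing, origin, "CT")
    # the prostate (subject origin) appears on CT where psi(x)=0 => x = T_r^{-1}(0)
    ct_center = rigid.inverse().apply(np.zeros(3))
    deform = make_deformation_field(spec, geometry, ct_center, rng)
    return rigid, deform


def generate_ct_phantom(mri_structures: StructureSet, true_rigid: RigidTransform,
                        true_deformation: Optional[DisplacementTransform],
                        spec: PhantomSpec):
    """Render the planning CT of the subject behind ``mri_structures``.

    Every CT voxel shows the subject-frame anatomy at the ground-truth
    mapped position ``psi(x) = T_r(x + d(x))``, so the CT structure masks
    are exactly the MRI masks pushed through the returned transform.
    Returns ``(ct, ct_structures, composite)``.
    """
    anatomy: Anatomy = getattr(mri_structures, "anatomy", None)
    if anatomy is None:
        raise ValueError("mri_structures must come from generate_mpmri_phantom")
    composite = CompositeTransform(true_rigid, true_deformation)
    rng = np.random.default_rng(spec.seed + 2_000_003)
    x, y, z, origin = _grid_coords(spec.large_shape, spec.large_spacing)
    pts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)
    mapped = composite.apply(pts)
    mx = mapped[:, 0].reshape(x.shape)
    my = mapped[:, 1].reshape(x.shape)
    mz = mapped[:, 2].reshape(x.shape)
    vals = anatomy.render(mx, my, mz, _CT, rng, spec.ct_noise_sd, poisson_like=True)
    ct = VolumeGrid(vals, spec.large_spacing, origin, "CT")
    masks = anatomy.masks_at(mx, my, mz)
    structures = StructureSet(reference=ct, structures={n: masks[n] for n in _CT_STRUCTS})
    return ct, structures, composite


def apply_intensity_drift(volume: VolumeGrid, gain: float, offset: float) -> VolumeGrid:
    """Affine scanner drift ``gain * I + offset`` clipped at zero."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return volume.with_values(np.clip(gain * volume.values + offset, 0, None))


@dataclass
class PhantomCase:
    """One complete synthetic case: mpMRI, planning MRI, CT, ground truth."""

    spec: PhantomSpec
    t2w: VolumeGrid
    adc: VolumeGrid
    structures: StructureSet
    t2w_large: VolumeGrid
    structures_large: StructureSet
    ct: VolumeGrid
    structures_ct: StructureSet
    true_transform: CompositeTransform


def make_phantom_case(spec: PhantomSpec) -> PhantomCase:
    """Generate every volume of one case from a single seed."""
    t2w, adc, structures = generate_mpmri_phantom(spec)
    t2w_large, structures_large = generate_large_fov(spec, structures.anatomy)
    structures_large.anatomy = structures.anatomy
    rigid, deform = sample_ground_truth_transform(spec)
    ct, structures_ct, composite = generate_ct_phantom(structures_large, rigid, deform, spec)
    return PhantomCase(spec, t2w, adc, structures, t2w_large, structures_large,
                       ct, structures_ct, composite)
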