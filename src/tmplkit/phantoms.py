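"""Synthetic T1-like head phantom populations with known ground-truth warps.

The generator emulates the statistical structure of an age- and sex-balanced
elderly cohort: five age strata with equal numbers of men and women, brain
extents near length 162 / width 132 / height 100 mm, smooth inter-subject
diffeomorphic shape variability, a multiplicative smooth bias field and
additive noise.  Anatomy is an analytic ellipsoidal head with a gray-matter
shell, white-matter core, a fluid ventricle and a handful of named deep
structures (thalamus-, hippocampus-, parahippocampal- and cerebellum-like
blobs, mirrored left/right where anatomy is paired).

Grid axis convention: axis 0 = length (anterior-posterior), axis 1 = width
(left-right), axis 2 = height (inferior-superior).

Each subject is built as: population-mean anatomy -> optional per-population
structure offsets -> global sex/stratum scale -> random smooth diffeomorphic
warp -> tissue-class intensity rendering -> multiplicative bias field ->
additive Gaussian noise.  The random warp is the exponential of a Gaussian-
smoothed white-noise velocity scaled so the mean displacement magnitude is
``warp_sd_mm``; it is recorded as ``true_warp`` (backward convention: it
warps the subject's demographic reference anatomy into the subject), the
deterministic sex/stratum scale being separate metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import LabelAtlas, TissueMaps, ValidationError, Volume, default_affine
from .registration import DeformationField, VelocityField, exp_velocity, identity_grid
from .deformation_metrics import jacobian_map

log = logging.getLogger(__name__)


class SpecificationError(ValueError):
    """A PhantomSpec is internally inconsistent (e.g. overlapping structures)."""


# tissue class codes in ascending intensity order
FLUID, GRAY, WHITE = 0, 1, 2
CLASS_NAMES = ("fluid", "gray", "white")


@dataclass
class Structure:
    """One anatomical blob: an ellipsoid offset from the brain centre (mm).

    ``mirror`` duplicates the blob across the width axis (left/right pair);
    ``pop_size_factor`` is a per-population multiplicative size offset used
    to emulate between-population morphology differences.
    """

    name: str
    center_mm: tuple          # (length, width, height) offset from brain centre
    semi_axes_mm: tuple
    tissue: int = GRAY
    mirror: bool = False
    pop_size_factor: float = 1.0


def default_structures():
    return [
        Structure("ventricle", (0.0, 0.0, 8.0), (20.0, 12.0, 9.0), tissue=FLUID),
        Structure("thalamus", (0.0, 12.0, 0.0), (9.0, 7.0, 7.0), tissue=GRAY, mirror=True),
        Structure("hippocampus", (-24.0, 24.0, -12.0), (13.0, 7.0, 7.0), tissue=GRAY, mirror=True),
        Structure("parahippocampal", (-22.0, 36.0, -22.0), (14.0, 9.0, 7.0), tissue=GRAY, mirror=True),
        Structure("cerebellum", (-52.0, 0.0, -26.0), (21.0, 27.0, 15.0), tissue=GRAY),
    ]


def default_strata():
    """Five 5-year age strata, 20 men and 20 women each (development-cohort design)."""
    return [(s, 20, 20) for s in ("60-64", "65-69", "70-74", "75-79", "80+")]


@dataclass
class PhantomSpec:
    """Geometry, intensity, noise and demographic design of a phantom population.

    brain_semi_axes_mm is ordered (width/2, length/2, height/2); defaults
    give extents 132 x 162 x 100 mm, inside the observed ranges of an
    elderly East-Asian cohort.  warp_sd_mm is the inter-subject deformation
    scale (mean displacement magnitude of the random warp), warp_smoothness_mm
    the Gaussian correlation length of its velocity.
    """

    grid_shape: tuple = (64, 64, 64)
    spacing_mm: float = 3.0
    brain_semi_axes_mm: tuple = (66.0, 81.0, 50.0)   # width/2, length/2, height/2
    structures: list = field(default_factory=default_structures)
    class_intensities: tuple = (0.3, 0.6, 0.9)       # fluid, gray, white
    shell_fraction: float = 0.15                     # outer radial fraction that is gray shell
    noise_sd: float = 0.03
    bias_amplitude: float = 0.2
    warp_sd_mm: float = 2.0
    warp_smoothness_mm: float = 12.0
    strata: list = field(default_factory=default_strata)
    sex_size_factor: float = 1.04                    # male/female global scale ratio
    stratum_shrink_per_step: float = 0.0             # optional linear shrink with age stratum

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s < 8 for s in self.grid_shape):
            raise SpecificationError("grid_shape axes must be >= 8")
        if self.spacing_mm <= 0:
            raise SpecificationError("spacing_mm must be positive")
        if any(a <= 0 for a in self.brain_semi_axes_mm):
            raise SpecificationError("brain semi-axes must be positive")
        for val, name in ((self.noise_sd, "noise_sd"), (self.bias_amplitude, "bias_amplitude"),
                          (self.warp_sd_mm, "warp_sd_mm")):
            if val < 0:
                raise SpecificationError(f"{name} must be >= 0")
        if self.warp_smoothness_mm <= 0:
            raise SpecificationError("warp_smoothness_mm must be positive")
        if self.sex_size_factor < 1:
            raise SpecificationError("sex_size_factor must be >= 1")
        for s in self.strata:
            if int(s[1]) < 0 or int(s[2]) < 0:
                raise SpecificationError("strata counts must be nonnegative integers")

    @property
    def spacing(self):
        return (self.spacing_mm,) * 3

    def affine(self):
        return default_affine(self.spacing, self.grid_shape)

    # semi-axes in grid-axis order (length, width, height)
    @property
    def semi_axes_grid_mm(self):
        w, l, h = self.brain_semi_axes_mm
        return (l, w, h)


def _expanded_structures(spec: PhantomSpec, population_scaled: bool):
    """Mirror paired structures; optionally apply per-population size offsets."""
    out = []
    for s in spec.structures:
        f = s.pop_size_factor if population_scaled else 1.0
        axes = tuple(a * f for a in s.semi_axes_mm)
        if s.mirror:
            cl, cw, ch = s.center_mm
            out.append(replace(s, name=s.name + "_l", center_mm=(cl, -abs(cw), ch),
                               semi_axes_mm=axes, mirror=False))
            out.append(replace(s, name=s.name + "_r", center_mm=(cl, abs(cw), ch),
                               semi_axes_mm=axes, mirror=False))
        else:
            out.append(replace(s, semi_axes_mm=axes))
    return out


def _world_coords_mm(spec: PhantomSpec):
    """Physical coordinates (mm, grid-axis order) of each voxel relative to grid centre."""
    grid = identity_grid(spec.grid_shape)
    centre = (np.asarray(spec.grid_shape, float) - 1) / 2.0
    return (grid - centre[:, None, None, None]) * spec.spacing_mm


def _anatomy_class_at(spec: PhantomSpec, coords_mm: np.ndarray, scale: float = 1.0,
                      population_scaled: bool = True) -> np.ndarray:
    """Tissue class code (-1 background) at physical coordinates.

    `scale` is the global demographic (sex/stratum) factor: the anatomy is
    the mean anatomy magnified by `scale` about the grid centre.
    """
    x = coords_mm / scale
    la, wa, ha = spec.semi_axes_grid_mm
    r2 = (x[0] / la) ** 2 + (x[1] / wa) ** 2 + (x[2] / ha) ** 2
    cls = np.full(x.shape[1:], -1, dtype=np.int8)
    brain = r2 <= 1.0
    shell = brain & (r2 > (1.0 - spec.shell_fraction) ** 2)
    cls[brain] = WHITE
    cls[shell] = GRAY
    for s in _expanded_structures(spec, population_scaled):
        c = np.asarray(s.center_mm)[:, None, None, None]
        a = np.asarray(s.semi_axes_mm)
        d2 = ((x[0] - c[0]) / a[0]) ** 2 + ((x[1] - c[1]) / a[1]) ** 2 + ((x[2] - c[2]) / a[2]) ** 2
        cls[(d2 <= 1.0) & brain] = s.tissue
    return cls


def _render(spec: PhantomSpec, cls: np.ndarray) -> np.ndarray:
    img = np.zeros(cls.shape)
    for code, intensity in enumerate(spec.class_intensities):
        img[cls == code] = intensity
    return img


def _tissue_maps(spec: PhantomSpec, cls: np.ndarray) -> TissueMaps:
    aff = spec.affine()
    maps = [Volume((cls == code).astype(np.float64), spec.spacing, aff, "probability")
            for code in range(len(spec.class_intensities))]
    bg = Volume((cls < 0).astype(np.float64), spec.spacing, aff, "probability")
    return TissueMaps(maps, bg, class_names=list(CLASS_NAMES))


@dataclass
class PhantomSubject:
    """One simulated participant: image, true tissue maps and ground-truth warp."""

    t1: Volume
    tissues: TissueMaps
    true_warp: DeformationField
    stratum: str
    sex: str
    subject_id: str
    scale: float = 1.0          # demographic (sex/stratum) global scale factor
    true_velocity: VelocityField = None
    clean_t1: Volume = None     # noise- and bias-free rendering, for oracles

    @property
    def channels(self):
        """T1 followed by the tissue probability maps (registration channels)."""
        return [self.t1] + list(self.tissues.maps)


def demographic_scale(spec: PhantomSpec, stratum, sex) -> float:
    scale = spec.sex_size_factor if sex == "M" else 1.0
    if spec.stratum_shrink_per_step:
        labels = [s[0] for s in spec.strata]
        step = labels.index(stratum) if stratum in labels else 0
        scale *= max(1.0 - spec.stratum_shrink_per_step * step, 0.1)
    return scale


def sample_velocity(spec: PhantomSpec, rng: np.random.Generator,
                    amplitude_mm: float = None) -> VelocityField:
    """Smoothed white-noise velocity scaled to a mean displacement magnitude."""
    amplitude_mm = spec.warp_sd_mm if amplitude_mm is None else amplitude_mm
    noise = rng.standard_normal((3,) + spec.grid_shape)
    if amplitude_mm == 0:
        return VelocityField(np.zeros_like(noise), spec.spacing, spec.affine(),
                             smoothness_mm=spec.warp_smoothness_mm)
    sigma_vox = spec.warp_smoothness_mm / spec.spacing_mm
    v = np.stack([ndimage.gaussian_filter(noise[c], sigma_vox) for c in range(3)])
    mean_norm = np.sqrt((v ** 2).sum(axis=0)).mean()
    v *= (amplitude_mm / spec.spacing_mm) / mean_norm
    return VelocityField(v, spec.spacing, spec.affine(),
                         smoothness_mm=spec.warp_smoothness_mm)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """exp of a random degree-2 polynomial in normalised coordinates, mean ~1."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    grid = identity_grid(spec.grid_shape)
    centre = (np.asarray(spec.grid_shape, float) - 1) / 2.0
    x = (grid - centre[:, None, None, None]) / centre[:, None, None, None]
    terms = [x[0], x[1], x[2], x[0] * x[1], x[0] * x[2], x[1] * x[2],
             x[0] ** 2, x[1] ** 2, x[2] ** 2]
    coeffs = rng.standard_normal(len(terms)) * spec.bias_amplitude / np.sqrt(len(terms))
    p = sum(c * t for c, t in zip(coeffs, terms))
    p -= p.mean()
    return np.exp(p)


def generate_subject(spec: PhantomSpec, stratum, sex, seed: int) -> PhantomSubject:
    """Deterministically simulate one participant (same inputs -> identical subject)."""
    if seed < 0:
        raise ValidationError("seed must be >= 0")
    if sex not in ("M", "F"):
        raise ValidationError(f"sex must be 'M' or 'F', got {sex!r}")
    rng = np.random.default_rng(seed)
    scale = demographic_scale(spec, stratum, sex)
    coords_mm = _world_coords_mm(spec)
    grid = identity_grid(spec.grid_shape)

    amplitude = spec.warp_sd_mm
    for attempt in range(5):
        vel = sample_velocity(spec, rng, amplitude_mm=amplitude)
        d = exp_velocity(vel)
        if amplitude == 0:
            break
        jac = jacobian_map(d, log_output=False, _validate=False)
        interior = jac.values[1:-1, 1:-1, 1:-1]
        if np.nanmin(interior) > 0:
            break
        amplitude *= 0.7
        log.warning("subject %s/%s seed %d: non-positive Jacobian, retrying with "
                    "warp amplitude %.2f mm", stratum, sex, seed, amplitude)
    else:
        raise ValidationError(f"could not draw an invertible warp after 5 attempts (seed {seed})")

    # evaluate the analytic anatomy at the warped coordinates: the subject
    # image at voxel x is the reference anatomy at x + u(x), exactly the
    # backward-warp semantics of true_warp
    centre = (np.asarray(spec.grid_shape, float) - 1) / 2.0
    warped_mm = (grid + d.displacement - centre[:, None, None, None]) * spec.spacing_mm
    cls = _anatomy_class_at(spec, warped_mm, scale=scale)
    clean = _render(spec, cls)
    tissues = _tissue_maps(spec, cls)
    bias = _bias_field(spec, rng)
    img = clean * bias
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    aff = spec.affine()
    return PhantomSubject(
        t1=Volume(img, spec.spacing, aff, "intensity"),
        tissues=tissues,
        true_warp=d,
        stratum=str(stratum),
        sex=sex,
        subject_id=f"{stratum}_{sex}_{seed}",
        scale=scale,
        true_velocity=vel,
        clean_t1=Volume(clean, spec.spacing, aff, "intensity"),
    )


def generate_population(spec: PhantomSpec, seed: int) -> list:
    """One subject per (stratum, sex, replicate) slot, distinct derived seeds.

    Subjects come back in deterministic order (stratum, then men, then women)
    with unique subject_ids.
    """
    if not spec.strata:
        raise SpecificationError("strata list is empty")
    ss = np.random.SeedSequence(seed)
    subjects = []
    k = 0
    for stratum, n_men, n_women in spec.strata:
        for sex, n in (("M", int(n_men)), ("F", int(n_women))):
            for rep in range(n):
                child = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
                subj = generate_subject(spec, stratum, sex, child)
                subj.subject_id = f"s{k:03d}_{stratum}_{sex}{rep}"
                subjects.append(subj)
                k += 1
    return subjects


def make_atlas(spec: PhantomSpec, overlap_tolerance: float = 0.33) -> LabelAtlas:
    """Deterministic label atlas on the population-mean anatomy.

    One label per named structure (left/right counted separately) plus an
    octant parcellation of the remaining brain tissue; at least 12 regions.
    Structure pairs overlapping by more than `overlap_tolerance` of the
    smaller member raise a SpecificationError naming the pair.
    """
    coords_mm = _world_coords_mm(spec)
    la, wa, ha = spec.semi_axes_grid_mm
    r2 = (coords_mm[0] / la) ** 2 + (coords_mm[1] / wa) ** 2 + (coords_mm[2] / ha) ** 2
    brain = r2 <= 1.0

    structures = _expanded_structures(spec, population_scaled=False)
    masks = []
    for s in structures:
        c = np.asarray(s.center_mm)[:, None, None, None]
        a = np.asarray(s.semi_axes_mm)
        d2 = (((coords_mm[0] - c[0]) / a[0]) ** 2 + ((coords_mm[1] - c[1]) / a[1]) ** 2
              + ((coords_mm[2] - c[2]) / a[2]) ** 2)
        masks.append((d2 <= 1.0) & brain)
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            inter = int((masks[i] & masks[j]).sum())
            smaller = max(min(int(masks[i].sum()), int(masks[j].sum())), 1)
            if inter / smaller > overlap_tolerance:
                raise SpecificationError(
                    f"structures {structures[i].name!r} and {structures[j].name!r} overlap by "
                    f"{inter / smaller:.0%} of the smaller one")

    labels = np.zeros(spec.grid_shape, dtype=np.int64)
    names = {}
    for idx, (s, m) in enumerate(zip(structures, masks), start=1):
        labels[m] = idx
        names[idx] = s.name
    rest = brain & (labels == 0)
    octant = (100 + (coords_mm[0] >= 0) * 4 + (coords_mm[1] >= 0) * 2 + (coords_mm[2] >= 0))
    labels[rest] = octant[rest]
    for o in range(100, 108):
        names[o] = (f"octant_{'ant' if (o - 100) & 4 else 'post'}_"
                    f"{'right' if (o - 100) & 2 else 'left'}_"
                    f"{'sup' if (o - 100) & 1 else 'inf'}")

    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    vox_vol = spec.spacing_mm ** 3
    regions = pd.DataFrame({
        "region_id": ids.astype(int),
        "name": [names[int(i)] for i in ids],
        "voxel_count": counts.astype(int),
        "volume_mm3": counts * vox_vol,
    })
    vol = Volume(labels, spec.spacing, spec.affine(), "label")
    return LabelAtlas(vol, regions)


def population_manifest(subjects, paths=None) -> pd.DataFrame:
    """Manifest table (subject_id, stratum, sex, scale [, file paths])."""
    rows = [{"subject_id": s.subject_id, "stratum": s.stratum, "sex": s.sex,
             "scale": s.scale} for s in subjects]
    df = pd.DataFrame(rows)
    if paths is not None:
        for col, vals in paths.items():
            df[col] = vals
    return df
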