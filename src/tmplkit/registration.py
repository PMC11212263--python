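"""Diffeomorphic registration on stationary velocity fields.

The deformation model is a stationary velocity field (SVF) v, exponentiated
to a diffeomorphism phi = exp(v) by scaling and squaring.  Displacements are
stored in *voxel units*, index order, backward (pull-back) convention: the
output-grid voxel x samples the input image at x + u(x).  exp(-v) is the
numerical inverse of exp(v), and the Jacobian determinant of exp(v) is
strictly positive for the smooth, moderate-amplitude fields this package
generates and estimates.

Pairwise registration is a greedy multiresolution diffeomorphic-demons
scheme on channel-weighted sum-of-squared-differences: at each iteration the
demons force is computed from the currently warped moving channels, smoothed
(fluid-like), applied to the velocity with a step size, and the accumulated
velocity is smoothed again (diffusion-like).  Steps that increase the
similarity are rejected and the step size halved, so the reported similarity
trace is non-increasing within each pyramid level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import GridMismatchError, ValidationError, Volume, default_affine

log = logging.getLogger(__name__)

_GRID_CACHE = {}


def identity_grid(shape) -> np.ndarray:
    """(3, ni, nj, nk) array of voxel indices; cached and read-only."""
    shape = tuple(int(s) for s in shape)
    grid = _GRID_CACHE.get(shape)
    if grid is None:
        grid = np.indices(shape, dtype=np.float64)
        grid.setflags(write=False)
        _GRID_CACHE[shape] = grid
    return grid


def sample_volume(values: np.ndarray, coords: np.ndarray, order: int = 1) -> np.ndarray:
    """Interpolate `values` at fractional voxel coordinates with edge clamping."""
    if order == 1:
        return _trilinear_many([values], coords)[0]
    return ndimage.map_coordinates(values, coords, order=order, mode="nearest")


def _trilinear_many(arrays, coords: np.ndarray):
    """Trilinear interpolation of several same-grid arrays at shared coordinates.

    Computing the 8 corner indices and weights once and reusing them across
    arrays (vector components, image channels) is what makes the demons
    iterations cheap; edge handling clamps to the border voxel, matching
    ``map_coordinates(mode='nearest')``.
    """
    shape = arrays[0].shape
    out_shape = coords.shape[1:]
    idx0 = []
    frac = []
    for a in range(3):
        c = np.clip(coords[a], 0.0, shape[a] - 1)
        f = np.floor(c)
        # keep the upper corner in range: at the top edge use the cell below
        f = np.minimum(f, shape[a] - 2) if shape[a] > 1 else f
        idx0.append(f.astype(np.intp))
        frac.append(c - f)
    i0, j0, k0 = idx0
    fx, fy, fz = frac
    gx, gy, gz = 1.0 - fx, 1.0 - fy, 1.0 - fz
    s1, s2 = shape[1] * shape[2], shape[2]
    base000 = (i0 * s1 + j0 * s2 + k0).ravel()
    offsets = ((0, gx * gy * gz), (1, gx * gy * fz), (s2, gx * fy * gz),
               (s2 + 1, gx * fy * fz), (s1, fx * gy * gz), (s1 + 1, fx * gy * fz),
               (s1 + s2, fx * fy * gz), (s1 + s2 + 1, fx * fy * fz))
    outs = []
    for arr in arrays:
        flat = arr.ravel()
        acc = np.zeros(base000.shape, dtype=np.float64)
        for off, w in offsets:
            acc += w.ravel() * flat[base000 + off]
        outs.append(acc.reshape(out_shape))
    return outs


def sample_field(vectors: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate each component of a (3,...) field at `coords`."""
    return np.stack(_trilinear_many(list(vectors), coords))


class RegistrationError(RuntimeError):
    """Similarity diverged or a precondition failed during optimisation."""


@dataclass
class VelocityField:
    """Stationary velocity field, voxel units, index order.

    ``smoothness_mm`` records the regularisation scale that produced it.
    ``diagnostics`` (when set by :func:`register`) holds per-level similarity
    traces.
    """

    vectors: np.ndarray
    spacing: tuple
    affine: np.ndarray
    smoothness_mm: float = 0.0
    diagnostics: dict = None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValidationError(f"velocity must be (3, ni, nj, nk), got {self.vectors.shape}")
        if not np.isfinite(self.vectors).all():
            raise ValidationError("velocity field contains non-finite components")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, float)

    @property
    def shape(self):
        return self.vectors.shape[1:]

    def negated(self) -> "VelocityField":
        return VelocityField(-self.vectors, self.spacing, self.affine, self.smoothness_mm)


@dataclass
class DeformationField:
    """Backward displacement field u: voxel x samples the input at x + u(x)."""

    displacement: np.ndarray
    spacing: tuple
    affine: np.ndarray

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
            raise ValidationError(
                f"displacement must be (3, ni, nj, nk), got {self.displacement.shape}")
        if not np.isfinite(self.displacement).all():
            raise ValidationError("deformation field contains non-finite components")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, float)

    @property
    def shape(self):
        return self.displacement.shape[1:]

    def same_grid(self, other, tol=1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol))


def identity_deformation(shape, spacing, affine=None) -> DeformationField:
    aff = default_affine(spacing, shape) if affine is None else affine
    return DeformationField(np.zeros((3,) + tuple(shape)), spacing, aff)


@dataclass
class RegistrationParams:
    """Hyperparameters of the multiresolution demons optimisation.

    iterations_per_level is ordered coarse -> fine and must have
    pyramid_levels entries.  velocity_smoothing_mm is the Gaussian scale
    applied to both the update and the accumulated velocity.
    """

    pyramid_levels: int = 3
    iterations_per_level: tuple = (30, 20, 10)
    update_step: float = 1.5
    velocity_smoothing_mm: float = None  # default: 2 x fine spacing, set at run time
    squaring_steps: int = None  # auto from max |v|
    similarity: str = "ssd"
    channel_weights: tuple = None  # default: equal

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValidationError("pyramid_levels must be >= 1")
        self.iterations_per_level = tuple(int(i) for i in self.iterations_per_level)
        if len(self.iterations_per_level) != self.pyramid_levels:
            raise ValidationError("iterations_per_level length must equal pyramid_levels")
        if any(i < 1 for i in self.iterations_per_level):
            raise ValidationError("iterations_per_level entries must be positive")
        if self.update_step <= 0:
            raise ValidationError("update_step must be positive")
        if self.similarity != "ssd":
            raise ValidationError("only ssd similarity is implemented")


# ---------------------------------------------------------------------------
# SVF exponential, composition, warping

def auto_squaring_steps(vectors: np.ndarray, requested=None) -> int:
    """Number of squarings so the initial step moves at most 0.5 voxel."""
    vmax = float(np.sqrt((vectors ** 2).sum(axis=0)).max())
    needed = 0 if vmax <= 0.5 else int(math.ceil(math.log2(vmax / 0.5)))
    if requested is None:
        return needed
    if requested < needed:
        log.info("squaring_steps raised from %d to %d (max |v| = %.3f voxels)",
                 requested, needed, vmax)
        return needed
    return int(requested)


def exp_velocity(v: VelocityField, squaring_steps=None) -> DeformationField:
    """phi = exp(v) by scaling and squaring: u0 = v / 2^N, then N self-compositions."""
    n = auto_squaring_steps(v.vectors, squaring_steps)
    u = v.vectors / float(2 ** n)
    grid = identity_grid(u.shape[1:])
    for _ in range(n):
        u = u + sample_field(u, grid + u)
    return DeformationField(u, v.spacing, v.affine)


def compose(outer: DeformationField, inner: DeformationField) -> DeformationField:
    """(outer o inner)(x) = u_outer(x) + u_inner(x + u_outer(x)).

    Warping an image by the result equals warping it by `inner` first and by
    `outer` second (backward convention).
    """
    if not outer.same_grid(inner):
        raise GridMismatchError("compose: fields must share one grid")
    grid = identity_grid(outer.shape)
    u = outer.displacement + sample_field(inner.displacement, grid + outer.displacement)
    return DeformationField(u, outer.spacing, outer.affine)


def warp(vol: Volume, d: DeformationField, interp: str = "linear",
         return_validity: bool = False):
    """Resample `vol` through d: out(x) = vol(x + u(x)).

    Out-of-bounds samples take the nearest edge value; when
    ``return_validity`` is set a companion boolean mask flags in-bounds
    voxels.  Label volumes must use nearest interpolation (the value set is
    preserved; no new labels are created).
    """
    if vol.shape != d.shape:
        raise GridMismatchError(f"warp: volume grid {vol.shape} != field grid {d.shape}")
    if vol.kind == "label" and interp != "nearest":
        raise ValidationError("label volumes must be warped with nearest interpolation")
    if interp not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    order = 1 if interp == "linear" else 0
    coords = identity_grid(vol.shape) + d.displacement
    out = sample_volume(vol.values.astype(np.float64), coords, order=order)
    if vol.kind == "label":
        out = np.rint(out).astype(vol.values.dtype)
    result = Volume(out, vol.spacing, vol.affine.copy(), vol.kind)
    if return_validity:
        valid = np.ones(vol.shape, dtype=bool)
        for c in range(3):
            valid &= (coords[c] >= 0) & (coords[c] <= vol.shape[c] - 1)
        return result, valid
    return result


def mean_displacement_voxels(d: DeformationField, mask: np.ndarray = None) -> float:
    mag = np.sqrt((d.displacement ** 2).sum(axis=0))
    return float(mag[mask].mean()) if mask is not None else float(mag.mean())


# ---------------------------------------------------------------------------
# Multiresolution demons registration

def _downsample(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    sm = ndimage.gaussian_filter(values, sigma=factor / 2.0)
    return ndimage.zoom(sm, 1.0 / factor, order=1, prefilter=False, grid_mode=False)


def _upsample_velocity(vec: np.ndarray, target_shape) -> np.ndarray:
    cur = np.asarray(vec.shape[1:], float)
    tgt = np.asarray(target_shape, float)
    factors = tgt / cur
    out = np.empty((3,) + tuple(target_shape))
    for c in range(3):
        # components are displacements along axis c: rescale with the grid
        out[c] = ndimage.zoom(vec[c], factors, order=1, prefilter=False,
                              grid_mode=False) * factors[c]
    return out


def _demons_force(warped, fixed, weights):
    """Channel-weighted demons update, voxel units.

    Per channel: f = diff * grad / (|grad|^2 + diff^2 + eps), the classic
    intensity-normalised step toward the fixed image.
    """
    eps = 1e-12
    force = np.zeros((3,) + fixed[0].shape)
    wsum = 0.0
    for wimg, fimg, w in zip(warped, fixed, weights):
        if w == 0:
            continue
        diff = wimg - fimg
        grad = np.stack(np.gradient(wimg))
        denom = (grad ** 2).sum(axis=0) + diff ** 2 + eps
        force += w * diff * grad / denom
        wsum += w
    return force / max(wsum, eps)


def _similarity(warped, fixed, weights):
    s, wsum = 0.0, 0.0
    for wimg, fimg, w in zip(warped, fixed, weights):
        s += w * float(((wimg - fimg) ** 2).mean())
        wsum += w
    return 0.5 * s / max(wsum, 1e-12)


def register(moving, fixed, params: RegistrationParams = None,
             init_velocity: "VelocityField" = None):
    """Register multichannel `moving` onto `fixed`; returns (velocity, deformation).

    Both arguments are lists of Volumes on one common grid; the returned
    deformation d satisfies warp(moving, d) ~= fixed, i.e. d maps the fixed
    (template) grid into the moving (subject) space in the backward
    convention.  The velocity's ``diagnostics`` carry the per-level
    similarity traces (monotone non-increasing within each level).
    `init_velocity` warm-starts the optimisation (resampled to the coarsest
    pyramid level), which groupwise construction uses to continue each
    subject's velocity across outer iterations.
    """
    params = params or RegistrationParams()
    if len(moving) != len(fixed):
        raise ValidationError(f"channel count mismatch: {len(moving)} moving vs {len(fixed)} fixed")
    if not moving:
        raise ValidationError("need at least one channel")
    ref = fixed[0]
    for vol in list(moving) + list(fixed):
        if not ref.same_grid(vol):
            raise GridMismatchError("all channels must share one grid")
    weights = params.channel_weights or (1.0,) * len(moving)
    if len(weights) != len(moving):
        raise ValidationError("channel_weights length must equal channel count")
    spacing = ref.spacing
    smoothing_mm = params.velocity_smoothing_mm
    if smoothing_mm is None:
        smoothing_mm = 2.0 * min(spacing)

    mov_data = [m.values.astype(np.float64) for m in moving]
    fix_data = [f.values.astype(np.float64) for f in fixed]

    traces = []
    v = None
    for level in range(params.pyramid_levels - 1, -1, -1):
        factor = 2 ** level
        if min(s // factor for s in ref.shape) < 4:
            # grid too small at this factor; skip to the next finer level
            traces.append([])
            continue
        mov_l = [_downsample(m, factor) for m in mov_data]
        fix_l = [_downsample(f, factor) for f in fix_data]
        shape_l = fix_l[0].shape
        level_spacing = min(spacing) * factor
        sigma = smoothing_mm / level_spacing
        if v is None:
            if init_velocity is not None:
                v = (_upsample_velocity(init_velocity.vectors, shape_l)
                     if init_velocity.vectors.shape[1:] != shape_l
                     else init_velocity.vectors.copy())
            else:
                v = np.zeros((3,) + shape_l)
        elif v.shape[1:] != shape_l:
            v = _upsample_velocity(v, shape_l)
        grid = identity_grid(shape_l)
        n_iter = params.iterations_per_level[params.pyramid_levels - 1 - level]
        step = params.update_step

        def _eval(vv):
            n = auto_squaring_steps(vv)
            u = vv / float(2 ** n)
            for _ in range(n):
                u = u + sample_field(u, grid + u)
            warped = _trilinear_many(mov_l, grid + u)
            return u, warped

        u, warped = _eval(v)
        sim = _similarity(warped, fix_l, weights)
        trace = [sim]
        for _ in range(n_iter):
            step = params.update_step
            force = _demons_force(warped, fix_l, weights)
            if sigma > 0.05:
                force = np.stack([ndimage.gaussian_filter(force[c], sigma) for c in range(3)])
            accepted = False
            for _try in range(6):
                # preferred step: diffusion-like smoothing of the accumulated
                # velocity; fallback keeps the fluid-smoothed update only, so
                # progress is still possible when re-smoothing v raises the
                # similarity (e.g. right after a pyramid upsample)
                candidates = [v - step * force]
                if sigma > 0.05:
                    candidates.insert(0, np.stack(
                        [ndimage.gaussian_filter(candidates[0][c], sigma) for c in range(3)]))
                for v_cand in candidates:
                    u_cand, warped_cand = _eval(v_cand)
                    sim_cand = _similarity(warped_cand, fix_l, weights)
                    if sim_cand <= sim + 1e-8:
                        v, u, warped, sim = v_cand, u_cand, warped_cand, sim_cand
                        accepted = True
                        break
                if accepted:
                    break
                step *= 0.5
            trace.append(sim)
            if not accepted:
                # step halving cannot reproduce the current state exactly
                # (the accumulated velocity is re-smoothed), so a persistent
                # tiny increase means a plateau, not divergence
                if sim_cand > 2.0 * sim + 1e-12 and sim_cand > trace[0]:
                    raise RegistrationError(
                        f"similarity diverged at level {level}: {sim:.3e} -> {sim_cand:.3e} "
                        f"after 5 step halvings (step={step:.2e})")
                log.debug("level %d converged early (no accepted step)", level)
                break
        traces.append(trace)

    vel = VelocityField(v, spacing, ref.affine.copy(), smoothness_mm=smoothing_mm,
                        diagnostics={"similarity_traces": traces})
    return vel, exp_velocity(vel)
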