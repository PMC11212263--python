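"""Preprocessing chain: canonical reorientation, isotropic reslicing,
polynomial bias-field correction, Gaussian-mixture tissue segmentation and
brain-extent measurement.

Landmark-based reorientation is replaced by principal-axis alignment (the
phantoms have no commissures): the head mask's principal axes are rotated
onto the grid axes — largest moment onto the length axis (axis 0), second
onto width (axis 1), third onto height (axis 2) — with the centroid moved to
the grid centre.  Extents are measured along grid axes of the canonically
oriented image, matching the "most inferior to most superior point" reading
of a height measurement.

Bias correction fits a low-order polynomial to log-intensities inside a
mask and divides it out; segmentation is a Gaussian intensity mixture fit by
EM inside the mask with k-means++-style initialisation (no spatial priors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

from .core_io import TissueMaps, ValidationError, Volume

log = logging.getLogger(__name__)


@dataclass
class ExtentMeasurement:
    """Whole-brain extents (mm) and their shape ratios W/L, H/L, H/W."""

    height_mm: float
    length_mm: float
    width_mm: float

    def __post_init__(self):
        if min(self.height_mm, self.length_mm, self.width_mm) <= 0:
            raise ValidationError("extents must be positive")

    @property
    def wl_ratio(self):
        return self.width_mm / self.length_mm

    @property
    def hl_ratio(self):
        return self.height_mm / self.length_mm

    @property
    def hw_ratio(self):
        return self.height_mm / self.width_mm


def default_mask_threshold(values: np.ndarray) -> float:
    """10% of the 99th intensity percentile — robust to the noise floor."""
    return 0.1 * float(np.percentile(values, 99))


def _head_mask(vol: Volume, mask_threshold) -> np.ndarray:
    thr = default_mask_threshold(vol.values) if mask_threshold is None else mask_threshold
    mask = vol.values > thr
    if not mask.any():
        raise ValidationError(f"threshold {thr} leaves an empty mask")
    return mask


def reorient_principal_axes(vol: Volume, mask_threshold: float = None,
                            degeneracy_ratio: float = 1.05):
    """Rotate the head so its principal axes align with the grid axes.

    Returns ``(reoriented volume, 4x4 rigid voxel transform)``.  The largest
    principal moment is mapped to axis 0 (length), the second to axis 1
    (width), the third to axis 2 (height), and the mask centroid to the grid
    centre.  Near-degenerate moments (adjacent eigenvalue ratio below
    `degeneracy_ratio`, e.g. a sphere) keep the identity rotation with a
    logged warning.
    """
    mask = _head_mask(vol, mask_threshold)
    pts = np.argwhere(mask).astype(float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)      # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    ratios = evals[:-1] / np.maximum(evals[1:], 1e-12)
    if np.any(ratios < degeneracy_ratio):
        log.warning("principal axes nearly degenerate (eigenvalue ratios %s); "
                    "keeping identity rotation", np.round(ratios, 3))
        rot = np.eye(3)
    else:
        rot = evecs
        # resolve sign/handedness: keep the rotation closest to identity
        for c in range(3):
            if rot[c, c] < 0:
                rot[:, c] *= -1
        if np.linalg.det(rot) < 0:
            rot[:, 2] *= -1
    centre = (np.asarray(vol.shape, float) - 1) / 2.0
    # output voxel x maps to input voxel rot @ (x - centre) + centroid
    offset = centroid - rot @ centre
    out = ndimage.affine_transform(vol.values.astype(float), rot, offset=offset,
                                   order=1, mode="constant", cval=0.0)
    rigid = np.eye(4)
    rigid[:3, :3] = rot
    rigid[:3, 3] = offset
    return Volume(out, vol.spacing, vol.affine.copy(), vol.kind), rigid


def resample_isotropic(vol: Volume, target_mm: float, interp: str = "linear") -> Volume:
    """Reslice to isotropic `target_mm` voxels covering the same world extent."""
    if target_mm <= 0:
        raise ValidationError("target_mm must be positive")
    if interp not in ("linear", "nearest"):
        raise ValidationError(f"unknown interpolation {interp!r}")
    factors = np.asarray(vol.spacing) / target_mm
    if np.allclose(factors, 1.0, atol=1e-12):
        return Volume(vol.values.copy(), (target_mm,) * 3, vol.affine.copy(), vol.kind)
    new_shape = np.maximum(np.round(np.asarray(vol.shape) * factors).astype(int), 1)
    # output voxel x samples input at x / factor (same world position)
    order = 1 if interp == "linear" else 0
    matrix = np.diag(1.0 / factors)
    out = ndimage.affine_transform(vol.values.astype(float), matrix, order=order,
                                   mode="nearest", output_shape=tuple(new_shape))
    new_affine = vol.affine.copy()
    new_affine[:3, :3] = vol.affine[:3, :3] @ np.diag(1.0 / factors)
    if vol.kind == "label":
        out = np.rint(out).astype(vol.values.dtype)
    return Volume(out, (target_mm,) * 3, new_affine, vol.kind)


def _poly_design(coords, degree):
    cols = [np.ones(coords.shape[1])]
    if degree >= 1:
        cols += [coords[i] for i in range(3)]
    if degree >= 2:
        cols += [coords[i] * coords[j] for i in range(3) for j in range(i, 3)]
    if degree >= 3:
        raise ValidationError("bias polynomial degree > 2 is not supported")
    return np.stack(cols, axis=1)


def bias_correct(vol: Volume, mask: Volume = None, degree: int = 2,
                 n_levels: int = 3, n_iter: int = 4):
    """Remove smooth multiplicative intensity inhomogeneity.

    Fits a degree-`degree` polynomial to log-intensities inside the mask and
    divides out its exponential.  To keep genuine tissue contrast out of the
    fit, log-intensities are detrended by per-class offsets: voxels are
    assigned to `n_levels` intensity classes (1D k-means on the current
    corrected values) and the polynomial is fit to the residual from the
    assigned class mean, alternating assignment and fit `n_iter` times.
    The corrected image keeps the original mean inside the mask exactly and
    the returned bias field (vol = corrected x bias) has mean ~1 there.
    Returns ``(corrected, bias)``.
    """
    if mask is None:
        m = _head_mask(vol, None)
    else:
        m = mask.values > 0.5
    if not m.any():
        raise ValidationError("bias correction mask is empty")
    vals = vol.values[m]
    if vals.min() <= 0:
        raise ValidationError("non-positive intensities inside the mask; "
                              "mask out background before bias correction")
    shape = np.asarray(vol.shape, float)
    idx = np.argwhere(m).astype(float).T
    coords = (idx - (shape[:, None] - 1) / 2) / np.maximum((shape[:, None] - 1) / 2, 1)
    X = _poly_design(coords, degree)
    logv = np.log(vals)
    fit = np.zeros_like(logv)
    for _ in range(n_iter):
        r = logv - fit
        lo, hi = r.min(), r.max()
        centers = lo + (np.arange(n_levels) + 0.5) / n_levels * (hi - lo)
        for _km in range(10):
            assign = np.argmin(np.abs(r[:, None] - centers[None, :]), axis=1)
            new = np.array([r[assign == k].mean() if (assign == k).any() else centers[k]
                            for k in range(n_levels)])
            if np.allclose(new, centers, atol=1e-9):
                break
            centers = new
        resid = logv - centers[assign]
        beta, *_ = np.linalg.lstsq(X, resid, rcond=None)
        fit = X @ beta

    full_idx = np.indices(vol.shape, dtype=float).reshape(3, -1)
    full_coords = (full_idx - (shape[:, None] - 1) / 2) / np.maximum((shape[:, None] - 1) / 2, 1)
    fitted = (_poly_design(full_coords, degree) @ beta).reshape(vol.shape)
    b0 = np.exp(fitted)
    # scale so the corrected mask mean equals the original mask mean exactly
    c = (vol.values[m] / b0[m]).mean() / vals.mean()
    bias = b0 * c
    corrected = vol.values / bias
    return (Volume(corrected, vol.spacing, vol.affine.copy(), vol.kind),
            Volume(bias, vol.spacing, vol.affine.copy(), "metric"))


class DegenerateMixtureError(ValueError):
    """The intensity distribution cannot support the requested mixture."""


def _kmeanspp_means(x, k, rng):
    means = [x[rng.integers(len(x))]]
    for _ in range(k - 1):
        d2 = np.min([(x - m) ** 2 for m in means], axis=0)
        p = d2 / d2.sum()
        means.append(x[rng.choice(len(x), p=p)])
    return np.sort(np.asarray(means))


def segment_tissues(vol: Volume, mask: Volume = None, n_classes: int = 3,
                    seed: int = 0, tol: float = 1e-6, max_iter: int = 200) -> TissueMaps:
    """Gaussian intensity-mixture segmentation inside a mask (no spatial priors).

    EM on a 1D `n_classes` Gaussian mixture, k-means++ initialisation;
    posterior probability maps come back ordered by ascending class mean,
    with background = 1 - mask, so the per-voxel class-plus-background sum
    is 1 within 1e-6.
    """
    if n_classes < 2:
        raise ValidationError("n_classes must be >= 2")
    m = _head_mask(vol, None) if mask is None else (mask.values > 0.5)
    if not m.any():
        raise ValidationError("segmentation mask is empty")
    x = vol.values[m].astype(float)
    if np.ptp(x) < 1e-12:
        raise DegenerateMixtureError("constant image inside mask; mixture is degenerate")
    rng = np.random.default_rng(seed)
    mu = _kmeanspp_means(x, n_classes, rng)
    var = np.full(n_classes, max(x.var() / n_classes ** 2, 1e-12))
    pi = np.full(n_classes, 1.0 / n_classes)
    prev_ll = -np.inf
    for it in range(max_iter):
        logp = (np.log(pi)[:, None] - 0.5 * np.log(2 * np.pi * var)[:, None]
                - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None])
        norm = logsumexp(logp, axis=0)
        ll = float(norm.mean())
        resp = np.exp(logp - norm[None, :])
        nk = resp.sum(axis=1) + 1e-12
        mu = (resp @ x) / nk
        var = np.maximum((resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk, 1e-10)
        pi = nk / nk.sum()
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    else:
        raise ValidationError(f"EM did not converge within {max_iter} iterations "
                              f"(last change {abs(ll - prev_ll):.2e})")
    order = np.argsort(mu)
    logp = (np.log(pi)[order, None] - 0.5 * np.log(2 * np.pi * var)[order, None]
            - 0.5 * (x[None, :] - mu[order, None]) ** 2 / var[order, None])
    resp = np.exp(logp - logsumexp(logp, axis=0)[None, :])
    maps = []
    for k in range(n_classes):
        vals = np.zeros(vol.shape)
        vals[m] = resp[k]
        maps.append(Volume(np.clip(vals, 0, 1), vol.spacing, vol.affine.copy(), "probability"))
    bg = Volume(1.0 - m.astype(float), vol.spacing, vol.affine.copy(), "probability")
    return TissueMaps(maps, bg)


def measure_extent(vol: Volume, mask_threshold: float = None) -> ExtentMeasurement:
    """World-space extents between extreme mask voxels along the grid axes.

    Axis 0 is length, axis 1 width, axis 2 height (canonical orientation);
    each extent is (max index - min index + 1) x spacing.
    """
    mask = _head_mask(vol, mask_threshold)
    nz = np.argwhere(mask)
    lo, hi = nz.min(axis=0), nz.max(axis=0)
    ext = (hi - lo + 1) * np.asarray(vol.spacing)
    return ExtentMeasurement(height_mm=float(ext[2]), length_mm=float(ext[0]),
                             width_mm=float(ext[1]))
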