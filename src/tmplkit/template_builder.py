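"""Groupwise unbiased template construction.

The template is built by iterating mean-and-register: start from the
voxelwise mean of rigidly imported subjects, register every subject to the
current template, warp the subjects into template space, average them, and
recentre the average by the inverse of the mean subject deformation so the
template drifts to the population's geometric centre ("unbiased": the mean
subject deformation is driven toward zero).  The outer/inner schedule
defaults to 6 outer iterations of 6 inner registration iterations per
pyramid level.

Recentring uses velocity-space averaging: the per-subject stationary
velocities are averaged and the template is warped by exp(-mean velocity),
the standard construction that keeps the recentring map diffeomorphic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import GridMismatchError, ValidationError, Volume
from .preprocess import default_mask_threshold
from .registration import (RegistrationParams, VelocityField, exp_velocity,
                           register, warp)

log = logging.getLogger(__name__)


@dataclass
class Template:
    """Population-average multichannel image with its construction history.

    channels: T1-like mean first, then one mean per tissue class, sharing
    one grid.  subject_deformations map template space into each subject
    (backward convention), taken from the final outer iteration.  history
    has one row per outer iteration actually run.
    """

    channels: list
    subject_deformations: list
    subject_velocities: list
    history: pd.DataFrame
    schedule: tuple
    subject_ids: list = field(default_factory=list)

    @property
    def t1(self) -> Volume:
        return self.channels[0]

    def brain_mask(self) -> np.ndarray:
        v = self.t1.values
        return v > default_mask_threshold(v)


def _subject_channels(subj):
    """Accept PhantomSubject-likes (``.channels``) or plain channel lists."""
    if hasattr(subj, "channels"):
        return list(subj.channels)
    return list(subj)


def _subject_id(subj, i):
    return getattr(subj, "subject_id", f"subject{i:03d}")


def _moments(values: np.ndarray, threshold: float):
    mask = values > threshold
    if not mask.any():
        raise ValidationError("empty head mask during initial import")
    pts = np.argwhere(mask).astype(float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    return mask, centroid, cov


def initial_import(subjects, threshold: float = None):
    """Rigid + isotropic-scale alignment of every subject to the first one.

    Moments-based: centroids are matched, principal axes aligned, and a
    global isotropic scale chosen from the head-mask volume ratio.  All
    channels are resampled onto the first subject's grid.  Returns
    ``(aligned channel sets, 4x4 voxel-space transforms)``.
    """
    if not subjects:
        raise ValidationError("initial_import needs at least one subject")
    channel_sets = [_subject_channels(s) for s in subjects]
    n_ch = len(channel_sets[0])
    for i, chs in enumerate(channel_sets):
        if len(chs) != n_ch:
            raise ValidationError(
                f"subject {_subject_id(subjects[i], i)} has {len(chs)} channels, expected {n_ch}")
    ref_t1 = channel_sets[0][0]
    thr = default_mask_threshold(ref_t1.values) if threshold is None else threshold
    _, ref_centroid, ref_cov = _moments(ref_t1.values, thr)
    ref_vol = float((ref_t1.values > thr).sum())

    aligned, transforms = [], []
    for i, chs in enumerate(channel_sets):
        t1 = chs[0]
        if i == 0:
            aligned.append([c.with_values(c.values.copy()) for c in chs])
            transforms.append(np.eye(4))
            continue
        mask, centroid, cov = _moments(t1.values, thr)
        scale = (float(mask.sum()) / ref_vol) ** (1.0 / 3.0)
        # principal-axis rotation, kept close to identity (phantom heads share
        # a canonical orientation; this absorbs small tilts only)
        re_vals, re_vecs = np.linalg.eigh(ref_cov)
        se_vals, se_vecs = np.linalg.eigh(cov)
        order_r, order_s = np.argsort(re_vals)[::-1], np.argsort(se_vals)[::-1]
        R = se_vecs[:, order_s] @ re_vecs[:, order_r].T
        for c in range(3):
            if R[c, c] < 0:
                R[:, c] *= -1
        if np.linalg.det(R) < 0:
            R[:, 2] *= -1
        # guard: degenerate moments make the rotation unreliable
        if np.min(re_vals[order_r][:-1] / np.maximum(re_vals[order_r][1:], 1e-12)) < 1.05:
            R = np.eye(3)
        A = scale * R
        offset = centroid - A @ ref_centroid
        tr = np.eye(4)
        tr[:3, :3] = A
        tr[:3, 3] = offset
        out_chs = []
        for ch in chs:
            order = 0 if ch.kind == "label" else 1
            vals = ndimage.affine_transform(ch.values.astype(float), A, offset=offset,
                                            order=order, mode="constant", cval=0.0,
                                            output_shape=ref_t1.shape)
            if ch.kind == "probability":
                vals = np.clip(vals, 0.0, 1.0)
            out_chs.append(Volume(vals, ref_t1.spacing, ref_t1.affine.copy(), ch.kind))
        aligned.append(out_chs)
        transforms.append(tr)
    return aligned, transforms


def template_sharpness(t1: Volume, mask: np.ndarray = None) -> float:
    """Mean gradient magnitude of the T1 channel over the brain mask."""
    g = np.stack(np.gradient(t1.values))
    mag = np.sqrt((g ** 2).sum(axis=0))
    if mask is None:
        mask = t1.values > default_mask_threshold(t1.values)
    return float(mag[mask].mean())


def _mean_channels(channel_sets):
    ref = channel_sets[0]
    out = []
    for c in range(len(ref)):
        mean_vals = np.mean([cs[c].values for cs in channel_sets], axis=0)
        kind = ref[c].kind if ref[c].kind != "label" else "intensity"
        out.append(Volume(mean_vals, ref[c].spacing, ref[c].affine.copy(), kind))
    return out


def build_template(imported, schedule=(6, 6), params: RegistrationParams = None,
                   recentre: bool = True, snapshot_callback=None,
                   subject_ids=None, warm_start: bool = False) -> Template:
    """Iterative mean-and-register groupwise template construction.

    `imported` is a list of per-subject channel lists on one common grid
    (see :func:`initial_import`).  ``schedule = (outer, inner)``: each outer
    iteration registers every subject to the current template running
    `inner` demons iterations per pyramid level, averages the warped
    subjects, and recentres by exp(-mean velocity).  `snapshot_callback`
    (outer_index, channels) can persist every intermediate template.

    With ``warm_start`` each outer pass continues the subject's velocity
    from the previous pass (minus the mean flow removed by recentring);
    registrations then converge cumulatively and the history displacement
    climbs toward the population's full deformation scale.  The default
    (cold start) spends the same fixed registration effort per outer
    iteration, so the history displacement is a like-for-like convergence
    diagnostic of the template itself.
    """
    outer, inner = int(schedule[0]), int(schedule[1])
    if outer < 1 or inner < 1:
        raise ValidationError("schedule (outer, inner) must both be >= 1")
    if len(imported) < 2:
        raise ValidationError("template construction needs at least 2 subjects")
    channel_sets = [_subject_channels(s) for s in imported]
    ref = channel_sets[0][0]
    for cs in channel_sets:
        for ch in cs:
            if not ref.same_grid(ch):
                raise GridMismatchError("all imported channels must share one grid")
    if params is None:
        params = RegistrationParams(pyramid_levels=3, iterations_per_level=(inner,) * 3)
    else:
        params = RegistrationParams(
            pyramid_levels=params.pyramid_levels,
            iterations_per_level=(inner,) * params.pyramid_levels,
            update_step=params.update_step,
            velocity_smoothing_mm=params.velocity_smoothing_mm,
            squaring_steps=params.squaring_steps,
            similarity=params.similarity,
            channel_weights=params.channel_weights)
    ids = list(subject_ids) if subject_ids is not None else [
        _subject_id(s, i) for i, s in enumerate(imported)]

    channels = _mean_channels(channel_sets)
    # fixed evaluation mask: history rows stay comparable across iterations
    eval_mask = channels[0].values > default_mask_threshold(channels[0].values)
    history = []
    deformations, velocities = [], []
    prev_velocities = [None] * len(channel_sets)
    for k in range(outer):
        deformations, velocities, warped_sets, sims = [], [], [], []
        for i, cs in enumerate(channel_sets):
            try:
                # warm-start from the previous outer iteration's velocity:
                # each outer pass refines the subject's flow against the
                # updated template instead of re-estimating it from scratch
                vel, d = register(cs, channels, params,
                                  init_velocity=prev_velocities[i] if warm_start else None)
            except Exception as exc:
                raise RuntimeError(
                    f"registration failed for subject {ids[i]} at outer iteration {k}: {exc}"
                ) from exc
            velocities.append(vel)
            deformations.append(d)
            warped_sets.append([warp(ch, d) for ch in cs])
            sims.append(vel.diagnostics["similarity_traces"][-1][-1])
        prev_velocities = velocities
        channels = _mean_channels(warped_sets)
        mean_vel_vec = np.mean([v.vectors for v in velocities], axis=0)
        if recentre and np.abs(mean_vel_vec).max() > 0:
            recentring = exp_velocity(VelocityField(
                -mean_vel_vec, ref.spacing, ref.affine.copy()))
            channels = [warp(ch, recentring) for ch in channels]
            # relative to the recentred template, each subject's flow is
            # (to first order) its old flow minus the mean flow
            prev_velocities = [VelocityField(v.vectors - mean_vel_vec, v.spacing,
                                             v.affine, v.smoothness_mm)
                               for v in velocities]
        sp = np.asarray(ref.spacing)[:, None, None, None]
        # convergence diagnostic: displacement of the *mean* deformation --
        # the template-drift component the recentring step drives to zero
        mean_u = np.mean([d.displacement for d in deformations], axis=0)
        drift_mm = float(np.sqrt(((mean_u * sp) ** 2).sum(axis=0))[eval_mask].mean())
        subj_disp_mm = float(np.mean(
            [np.sqrt(((d.displacement * sp) ** 2).sum(axis=0))[eval_mask].mean()
             for d in deformations]))
        history.append({"outer_iteration": k, "mean_displacement_mm": drift_mm,
                        "mean_subject_displacement_mm": subj_disp_mm,
                        "mean_similarity": float(np.mean(sims)),
                        "sharpness": template_sharpness(channels[0], eval_mask)})
        log.info("outer %d/%d: mean (drift) displacement %.4f mm, per-subject %.3f mm, "
                 "similarity %.3e", k + 1, outer, drift_mm, subj_disp_mm,
                 history[-1]["mean_similarity"])
        if snapshot_callback is not None:
            snapshot_callback(k, channels)
    return Template(channels=channels, subject_deformations=deformations,
                    subject_velocities=velocities, history=pd.DataFrame(history),
                    schedule=(outer, inner), subject_ids=ids)
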