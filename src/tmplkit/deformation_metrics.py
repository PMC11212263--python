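"""Per-voxel deformation metrics and atlas region summaries.

Two quantities measure the deformation a normalization imposes on a scan:

* displacement magnitude — the Euclidean distance, in mm, between a voxel's
  original and normalized positions, ``sqrt(sum_i (u_i * spacing_i)^2)``;
* the Jacobian determinant of the mapping ``phi(x) = x + u(x)`` — the local
  volume-change factor, ``det(I + grad u)`` in index space (voxel spacing
  cancels in the determinant of the index-space map).  The natural log of J
  is signed (log J > 0 is expansion); its absolute value weights expansion
  and contraction equally so that region means do not cancel.

Maps computed in different template spaces are transported to one common
reference grid through a bridge deformation before any cross-template
statistic is taken.  Region summaries average each map over atlas labels and
drop regions below a minimum volume (default 500 mm^3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import GridMismatchError, LabelAtlas, ValidationError, Volume
from .registration import DeformationField, warp


def displacement_map(d: DeformationField) -> Volume:
    """Euclidean displacement magnitude in mm at every voxel (kind=metric)."""
    sp = np.asarray(d.spacing)[:, None, None, None]
    mag = np.sqrt(((d.displacement * sp) ** 2).sum(axis=0))
    return Volume(mag, d.spacing, d.affine.copy(), "metric")


def jacobian_map(d: DeformationField, log_output: bool = False,
                 nonpositive_fraction_limit: float = 0.01, _validate: bool = True):
    """Jacobian determinant det(I + grad u) of the deformation, per voxel.

    Gradients use central differences (one-sided at the boundary).  Voxels
    with det <= 1e-6 are set missing (NaN) and counted in
    ``result.meta['n_nonpositive']``.  If more than
    `nonpositive_fraction_limit` of *interior* voxels are non-positive the
    field is not plausibly diffeomorphic and an error is raised (disabled by
    ``_validate=False`` for callers that screen fields themselves).
    """
    u = d.displacement
    jac = np.empty((3, 3) + u.shape[1:])
    for i in range(3):
        g = np.gradient(u[i], axis=(0, 1, 2))
        for j in range(3):
            jac[i, j] = g[j]
        jac[i, i] += 1.0
    det = (jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
           - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
           + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0]))
    bad = det <= 1e-6
    n_bad = int(bad.sum())
    if _validate:
        interior_bad = bad[1:-1, 1:-1, 1:-1]
        frac = interior_bad.mean() if interior_bad.size else 0.0
        if frac > nonpositive_fraction_limit:
            raise ValidationError(
                f"{frac:.1%} of interior voxels have non-positive Jacobian determinant; "
                "field is not diffeomorphic")
    out = det.copy()
    if log_output:
        out = np.where(bad, np.nan, np.log(np.where(bad, 1.0, det)))
    else:
        out = np.where(bad, np.nan, det)
    vol = Volume(out, d.spacing, d.affine.copy(), "metric")
    vol.meta["n_nonpositive"] = n_bad
    vol.meta["log"] = bool(log_output)
    vol.meta["log_base"] = "e" if log_output else None
    return vol


def abs_log_jacobian(logj: Volume) -> Volume:
    """Voxelwise |log J|; missing (NaN) voxels propagate."""
    if logj.kind != "metric":
        raise ValidationError("abs_log_jacobian expects a metric volume")
    out = Volume(np.abs(logj.values), logj.spacing, logj.affine.copy(), "metric")
    out.meta.update(logj.meta)
    return out


def to_common_space(map_vol: Volume, bridge: DeformationField,
                    return_validity: bool = False):
    """Resample a metric map onto the common reference grid through `bridge`.

    `bridge` maps the common-reference grid into the map's space (backward
    convention), so this is exactly a linear-interpolation warp; the
    companion validity mask flags voxels whose sample stayed in bounds.
    """
    if map_vol.shape != bridge.shape:
        raise GridMismatchError(
            f"bridge grid {bridge.shape} does not match reference/map grid {map_vol.shape}")
    return warp(map_vol, bridge, interp="linear", return_validity=return_validity)


def region_summary(map_displacement: Volume, map_abslogj: Volume, atlas: LabelAtlas,
                   min_volume_mm3: float = 500.0) -> pd.DataFrame:
    """Mean displacement and |log J| per retained atlas region.

    Regions whose total volume is below `min_volume_mm3` are dropped (the
    small-region exclusion rule); missing-valued voxels are excluded from
    the means and reflected in ``n_voxels_used``.
    """
    if not map_displacement.same_grid(atlas.labels):
        raise GridMismatchError("displacement map and atlas must share one grid")
    if not map_abslogj.same_grid(atlas.labels):
        raise GridMismatchError("|log J| map and atlas must share one grid")
    keep = atlas.regions[atlas.regions["volume_mm3"] >= min_volume_mm3]
    if keep.empty:
        raise ValidationError(
            f"no region survives the {min_volume_mm3} mm^3 volume threshold")
    labels = atlas.labels.values
    rows = []
    for _, reg in keep.iterrows():
        sel = labels == int(reg["region_id"])
        row = {"region_id": int(reg["region_id"]), "name": reg["name"],
               "volume_mm3": float(reg["volume_mm3"])}
        for col, vol in (("mean_displacement_mm", map_displacement),
                         ("mean_abs_log_jacobian", map_abslogj)):
            vals = vol.values[sel]
            good = np.isfinite(vals)
            row[col] = float(vals[good].mean()) if good.any() else np.nan
            row[f"n_voxels_used_{col}"] = int(good.sum())
        row["n_voxels_used"] = min(row["n_voxels_used_mean_displacement_mm"],
                                   row["n_voxels_used_mean_abs_log_jacobian"])
        rows.append(row)
    return pd.DataFrame(rows)
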