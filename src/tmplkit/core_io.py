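"""Image data model and NIfTI input/output.

All geometry in this package follows one convention: voxel indices are
0-based, and the 4x4 affine maps voxel indices to world (mm) coordinates as
in the NIfTI-1 standard.  Scalar images live in :class:`Volume`; per-voxel
3-vector fields (deformations, velocities) are stored on disk as 4D NIfTI
with the vector dimension last, components in *voxel units* and index order,
and in memory as ``(3, ni, nj, nk)`` arrays (components first, which is what
``scipy.ndimage.map_coordinates`` expects).

Internal computation is double precision; on-disk scalars are 32-bit float
and labels the smallest sufficient unsigned integer.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

VOLUME_KINDS = ("intensity", "probability", "label", "metric")


class FormatError(ValueError):
    """File is not a NIfTI image or its header cannot be interpreted."""


class ValidationError(ValueError):
    """A domain invariant is violated (non-finite values, bad probabilities...)."""


class GridMismatchError(ValueError):
    """Two objects that must share a grid do not."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and a voxel-to-world transform.

    Parameters
    ----------
    values : ndarray, shape (ni, nj, nk)
        Scalar grid.  Finite everywhere, except ``kind='metric'`` where NaN
        marks missing voxels (e.g. non-positive Jacobian determinants).
    spacing : tuple of 3 floats
        Voxel edge length in mm along each grid axis; all positive.
    affine : ndarray, shape (4, 4)
        Voxel-index -> mm world transform (NIfTI convention).
    kind : {'intensity', 'probability', 'label', 'metric'}
    """

    values: np.ndarray
    spacing: tuple
    affine: np.ndarray
    kind: str = "intensity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"Volume values must be 3D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if self.kind not in VOLUME_KINDS:
            raise ValidationError(f"kind must be one of {VOLUME_KINDS}, got {self.kind!r}")
        if self.kind == "metric":
            if np.isinf(self.values).any():
                raise ValidationError("metric volume contains infinities")
        elif not np.isfinite(self.values).all():
            raise ValidationError(f"{self.kind} volume contains non-finite values")
        if self.kind == "probability":
            if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
                raise ValidationError("probability volume has values outside [0, 1]")
        if self.kind == "label":
            v = self.values
            if not np.issubdtype(v.dtype, np.integer):
                if not np.all(v == np.round(v)) or v.min() < 0:
                    raise ValidationError("label volume must hold nonnegative integers")
                self.values = v.astype(np.int64)
            elif v.min() < 0:
                raise ValidationError("label volume must hold nonnegative integers")

    @property
    def shape(self):
        return self.values.shape

    def same_grid(self, other, tol: float = 1e-6) -> bool:
        """True when shape, spacing and world transform agree within `tol`."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.affine, other.affine, atol=tol)
        )

    def with_values(self, values, kind=None) -> "Volume":
        """New Volume on the same grid with different values (inputs never mutated)."""
        return Volume(np.asarray(values), self.spacing, self.affine.copy(),
                      kind or self.kind)


@dataclass
class LabelAtlas:
    """Integer-label parcellation plus its region table.

    ``regions`` has columns region_id, name, voxel_count, volume_mm3 with
    volume_mm3 = voxel_count x voxel volume exactly; every nonzero label in
    the grid appears in the table and vice versa.
    """

    labels: Volume
    regions: pd.DataFrame

    def __post_init__(self):
        if self.labels.kind != "label":
            raise ValidationError("atlas labels must be a label volume")
        need = {"region_id", "name", "voxel_count", "volume_mm3"}
        if not need.issubset(self.regions.columns):
            raise ValidationError(f"region table must have columns {sorted(need)}")
        vox_vol = float(np.prod(self.labels.spacing))
        expect = self.regions["voxel_count"].to_numpy() * vox_vol
        if not np.allclose(self.regions["volume_mm3"].to_numpy(), expect, rtol=0, atol=1e-9):
            raise ValidationError("volume_mm3 != voxel_count * voxel volume")
        in_grid = set(np.unique(self.labels.values)) - {0}
        in_table = set(int(r) for r in self.regions["region_id"])
        if in_grid != in_table:
            raise ValidationError(
                f"label grid / region table mismatch: only-grid={sorted(in_grid - in_table)}, "
                f"only-table={sorted(in_table - in_grid)}")


@dataclass
class TissueMaps:
    """Ordered per-class probability maps (ascending mean intensity) plus background.

    All maps share one grid and sum to 1 per voxel within 1e-6 (background
    included).  ``maps[i]`` is the i-th tissue class; ``background`` is the
    non-head complement.
    """

    maps: list
    background: Volume
    class_names: list = None

    def __post_init__(self):
        if not self.maps:
            raise ValidationError("TissueMaps needs at least one class map")
        ref = self.maps[0]
        for m in list(self.maps) + [self.background]:
            if m.kind != "probability":
                raise ValidationError("tissue maps must be probability volumes")
            if not ref.same_grid(m):
                raise GridMismatchError("tissue maps must share one grid")
        total = sum(m.values for m in self.maps) + self.background.values
        if np.abs(total - 1.0).max() > 1e-6:
            raise ValidationError("tissue class probabilities must sum to 1 per voxel")
        if self.class_names is None:
            self.class_names = [f"class{i}" for i in range(len(self.maps))]


# ---------------------------------------------------------------------------
# NIfTI I/O

def _spacing_from_img(img) -> tuple:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_volume(path, kind: str = "intensity"):
    """Read a NIfTI file.

    3D images come back as a :class:`Volume`; 4D images whose last dimension
    has length 3 come back as the raw vector grid ``(ni, nj, nk, 3)`` ndarray
    (see :func:`read_field` for the typed wrapper).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several wrapper-specific errors
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 3:
        return data.astype(np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D scalar or 4D 3-vector image, got shape {data.shape}")
    if kind == "label":
        data = np.rint(data).astype(np.int64)
    else:
        data = data.astype(np.float64)
    return Volume(data, _spacing_from_img(img), np.asarray(img.affine, float), kind)


def write_volume(vol: Volume, path) -> Path:
    """Write a Volume as NIfTI (.nii or .nii.gz); returns the path written.

    Scalars go to float32, labels to the smallest sufficient unsigned int.
    Non-finite values are rejected up front except for metric maps, where NaN
    encodes missing voxels.
    """
    path = Path(path)
    vals = vol.values
    if vol.kind == "metric":
        if np.isinf(vals).any():
            raise ValidationError("refusing to write metric volume with infinities")
    elif not np.isfinite(vals).all():
        raise ValidationError(f"refusing to write {vol.kind} volume with non-finite values")
    if vol.kind == "label":
        vmax = int(vals.max()) if vals.size else 0
        dtype = np.uint8 if vmax < 2**8 else (np.uint16 if vmax < 2**16 else np.uint32)
        out = vals.astype(dtype)
    else:
        out = vals.astype(np.float32)
    img = nib.Nifti1Image(out, vol.affine)
    img.header.set_zooms(vol.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_field(vectors: np.ndarray, spacing, affine, path, convention: str = "backward") -> Path:
    """Write a per-voxel 3-vector field as 4D NIfTI (vector dim last, voxel units).

    A JSON sidecar records the displacement convention and units so a field's
    direction is part of its on-disk metadata.
    """
    vectors = np.asarray(vectors)
    if vectors.ndim != 4 or vectors.shape[0] != 3:
        raise ValidationError(f"expected (3, ni, nj, nk) vector grid, got {vectors.shape}")
    if not np.isfinite(vectors).all():
        raise ValidationError("refusing to write non-finite vector field")
    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(vectors, 0, -1).astype(np.float32), np.asarray(affine, float))
    img.header.set_intent("vector")
    img.header.set_zooms(tuple(spacing) + (1.0,))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    with open(str(sidecar) + ".json", "w") as fh:
        json.dump({"convention": convention, "units": "voxel", "vector_axis": "last"}, fh)
    return path


def read_field(path):
    """Read a 4D vector NIfTI written by :func:`write_field`.

    Returns ``(vectors (3, ni, nj, nk), spacing, affine)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such field: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: expected 4D image with 3 components last, got {data.shape}")
    return (np.moveaxis(data, -1, 0).astype(np.float64),
            _spacing_from_img(img), np.asarray(img.affine, float))


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a report table as TSV with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def default_affine(spacing, shape=None) -> np.ndarray:
    """Diagonal voxel->mm affine, origin at the grid centre when shape given."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    if shape is not None:
        aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * np.asarray(spacing)
    return aff
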