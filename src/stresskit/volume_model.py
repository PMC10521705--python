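"""Core data types, NIfTI I/O, mask geometry, and rigid spatial transforms.

Conventions
-----------
Voxel indices are 0-based with axis order (X, Y, Z) mapping anatomically to
(left-right, anterior-posterior, inferior-superior).  All studies live on a
common isotropic grid (1 voxel = 1 mm by default), are skull-stripped, and
have exactly-zero background.  Rotations are taken about the geometric
center of the grid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage


class SequenceKind(str, enum.Enum):
    """The four standard brain-tumor MRI sequences, in canonical channel order."""

    T1W = "T1W"
    T1GD = "T1Gd"
    T2W = "T2W"
    FLAIR = "FLAIR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical channel-stacking order.
SEQUENCE_ORDER: tuple[SequenceKind, ...] = (
    SequenceKind.T1W,
    SequenceKind.T1GD,
    SequenceKind.T2W,
    SequenceKind.FLAIR,
)


class GridIncompatibilityError(ValueError):
    """Raised when volumes or masks do not share one grid."""


class MissingChannelError(KeyError):
    """Raised when a required MRI sequence is absent from a study."""


class EmptyMaskError(ValueError):
    """Raised when a mask that must be non-empty is empty."""


@dataclass
class Volume:
    """One 3D scalar channel on an isotropic grid.

    Parameters
    ----------
    data:
        3D float array; arbitrary intensity units, background exactly 0.
    spacing:
        Voxel size in mm along (X, Y, Z); strictly positive.
    affine:
        Optional 4x4 voxel-to-world matrix kept for NIfTI round-trips.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite everywhere")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(
            self.data.copy(),
            tuple(self.spacing),
            None if self.affine is None else self.affine.copy(),
        )


#: Axis roles on Volume grids: X = left-right (phase encoding by default),
#: Y = anterior-posterior (frequency encoding), Z = inferior-superior.
AXIS_ROLES: Mapping[str, int] = {"left-right": 0, "anterior-posterior": 1, "inferior-superior": 2}


@dataclass
class Study:
    """A four-sequence volumetric study with brain and tumor masks.

    All volumes and masks share one grid shape and spacing; the tumor mask
    is a subset of the brain mask.  ``grade_label`` records whether the
    lesion is GBM-like (rim-enhancing) or LGG-like (diffuse, non-enhancing).
    """

    subject_id: str
    sequences: dict[SequenceKind, Volume]
    brain_mask: np.ndarray
    tumor_mask: np.ndarray
    grade_label: str = "unknown"

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        shapes = {v.shape for v in self.sequences.values()}
        shapes |= {self.brain_mask.shape, self.tumor_mask.shape}
        if len(shapes) != 1:
            raise GridIncompatibilityError(f"inconsistent grid shapes: {sorted(shapes)}")
        if np.any(self.tumor_mask & ~self.brain_mask):
            raise ValueError("tumor_mask must be a subset of brain_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape

    def volume(self, kind: SequenceKind) -> Volume:
        try:
            return self.sequences[kind]
        except KeyError:
            raise MissingChannelError(f"study {self.subject_id!r} lacks sequence {kind}") from None

    def copy(self) -> "Study":
        return Study(
            subject_id=self.subject_id,
            sequences={k: v.copy() for k, v in self.sequences.items()},
            brain_mask=self.brain_mask.copy(),
            tumor_mask=self.tumor_mask.copy(),
            grade_label=self.grade_label,
        )


@dataclass
class RigidTransform:
    """A pure rigid-body transform (no scaling or shear).

    ``rot_updown_deg`` nods the chin up/down (rotation about the X axis);
    ``rot_leftright_deg`` shakes the head left/right (rotation about the Z
    axis).  Translation is in voxels along (X, Y, Z).
    """

    rot_updown_deg: float = 0.0
    rot_leftright_deg: float = 0.0
    translation_px: tuple[float, float, float] = (0.0, 0.0, 0.0)
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        vals = [self.rot_updown_deg, self.rot_leftright_deg, *self.translation_px]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite rigid transform parameters: {vals}")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError(f"interpolation must be 'linear' or 'nearest', got {self.interpolation!r}")

    @property
    def is_identity(self) -> bool:
        return (
            self.rot_updown_deg == 0.0
            and self.rot_leftright_deg == 0.0
            and all(t == 0.0 for t in self.translation_px)
        )

    def rotation_matrix(self) -> np.ndarray:
        """Net rotation matrix, chin nod applied first, then head shake."""
        a = np.deg2rad(self.rot_updown_deg)
        b = np.deg2rad(self.rot_leftright_deg)
        rx = np.array(
            [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
        )
        rz = np.array(
            [[np.cos(b), -np.sin(b), 0], [np.sin(b), np.cos(b), 0], [0, 0, 1]]
        )
        return rz @ rx

    def inverse(self) -> "RigidTransform":
        """Inverse transform in angle form.

        Exact for a pure translation or a single-axis rotation; a combined
        transform has no representation in this (chin-first) angle
        parameterization — use :func:`apply_rigid_inverse` instead.
        """
        no_rot = self.rot_updown_deg == 0.0 and self.rot_leftright_deg == 0.0
        no_tr = all(t == 0.0 for t in self.translation_px)
        one_axis = self.rot_updown_deg == 0.0 or self.rot_leftright_deg == 0.0
        if no_rot:
            tx, ty, tz = self.translation_px
            return replace(self, translation_px=(-tx, -ty, -tz))
        if no_tr and one_axis:
            return replace(
                self,
                rot_updown_deg=-self.rot_updown_deg,
                rot_leftright_deg=-self.rot_leftright_deg,
            )
        raise NotImplementedError(
            "angle-form inverse exists only for a pure translation or a "
            "single-axis rotation; use apply_rigid_inverse for the general case"
        )


def apply_rigid(volume: Volume, transform: RigidTransform) -> Volume:
    """Resample ``volume`` under a rigid map about the grid center.

    Out-of-field voxels are filled with 0 (skull-stripped background).  The
    identity transform with nearest interpolation returns the input exactly.
    """
    if transform.is_identity and transform.interpolation == "nearest":
        return volume.copy()
    order = 1 if transform.interpolation == "linear" else 0
    rot = transform.rotation_matrix()
    center = (np.asarray(volume.shape, dtype=float) - 1.0) / 2.0
    t = np.asarray(transform.translation_px, dtype=float)
    # Forward map p -> R (p - c) + c + t; ndimage wants the inverse map.
    matrix = rot.T
    offset = center - matrix @ (center + t)
    out = ndimage.affine_transform(
        volume.data, matrix, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=False,
    )
    return Volume(out, tuple(volume.spacing), None if volume.affine is None else volume.affine.copy())


def apply_rigid_inverse(volume: Volume, transform: RigidTransform) -> Volume:
    """Resample under the exact inverse of ``transform``'s rigid map.

    ``apply_rigid_inverse(apply_rigid(v, T), T)`` restores ``v`` up to
    interpolation error; works for any rigid transform, including
    combined rotation + translation.
    """
    if transform.is_identity and transform.interpolation == "nearest":
        return volume.copy()
    order = 1 if transform.interpolation == "linear" else 0
    rot = transform.rotation_matrix()
    center = (np.asarray(volume.shape, dtype=float) - 1.0) / 2.0
    t = np.asarray(transform.translation_px, dtype=float)
    # Forward map F(p) = R (p - c) + c + t; here the sampling map is F itself.
    offset = center + t - rot @ center
    out = ndimage.affine_transform(
        volume.data, rot, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=False,
    )
    return Volume(out, tuple(volume.spacing), None if volume.affine is None else volume.affine.copy())


def brain_mask_from(volume: Volume) -> np.ndarray:
    """Positive-support brain mask, largest connected component only.

    Skull-stripped inputs have zero background, so the brain is the largest
    connected region of strictly positive intensity; isolated bright specks
    are discarded.
    """
    support = volume.data > 0
    if not support.any():
        raise EmptyMaskError("volume has no positive voxels; cannot derive brain mask")
    labels, n = ndimage.label(support)
    if n == 1:
        return support
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def distance_outside(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance (voxels) from each outside voxel to the mask; 0 inside."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("distance_outside requires a non-empty mask")
    return ndimage.distance_transform_edt(~mask)


def _nifti_affine(volume: Volume) -> np.ndarray:
    if volume.affine is not None:
        return volume.affine
    return np.diag([*volume.spacing, 1.0])


def save_study(study: Study, directory: str | Path) -> dict[str, Path]:
    """Write one NIfTI per sequence plus the two masks; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind in SEQUENCE_ORDER:
        if kind not in study.sequences:
            continue
        vol = study.sequences[kind]
        p = directory / f"{study.subject_id}_{kind.value}.nii.gz"
        nib.save(nib.Nifti1Image(vol.data, _nifti_affine(vol)), p)
        paths[kind.value] = p
    spacing = next(iter(study.sequences.values())).spacing
    aff = _nifti_affine(next(iter(study.sequences.values())))
    for name, mask in (("brain_mask", study.brain_mask), ("tumor_mask", study.tumor_mask)):
        p = directory / f"{study.subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), aff), p)
        paths[name] = p
    del spacing
    return paths


def load_study(
    paths: Mapping[SequenceKind, str | Path],
    tumor_mask_path: str | Path,
    subject_id: str,
    brain_mask_path: str | Path | None = None,
    grade_label: str = "unknown",
) -> Study:
    """Load a four-sequence study from NIfTI files on one common grid.

    The brain mask is derived from the summed sequences (positive support,
    largest component) unless ``brain_mask_path`` is given.  Affines are
    kept so that ``save_study(load_study(...))`` is voxel-identical.
    """
    sequences: dict[SequenceKind, Volume] = {}
    for kind in SEQUENCE_ORDER:
        if kind not in paths:
            raise MissingChannelError(f"missing sequence {kind} in load_study paths")
        img = nib.load(str(paths[kind]))
        data = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        sequences[kind] = Volume(data, spacing, np.asarray(img.affine))
    shapes = {v.shape for v in sequences.values()}
    timg = nib.load(str(tumor_mask_path))
    tumor = np.asarray(timg.dataobj) > 0
    shapes.add(tumor.shape)
    if len(shapes) != 1:
        raise GridIncompatibilityError(f"inputs on different grids: {sorted(shapes)}")
    if brain_mask_path is not None:
        brain = np.asarray(nib.load(str(brain_mask_path)).dataobj) > 0
    else:
        total = Volume(
            sum(v.data for v in sequences.values()),
            sequences[SequenceKind.T1W].spacing,
        )
        brain = brain_mask_from(total)
        # Ensure tumor ⊆ brain even if a lesion channel is dark on every sequence.
        brain |= tumor
    return Study(
        subject_id=subject_id,
        sequences=sequences,
        brain_mask=brain,
        tumor_mask=tumor,
        grade_label=grade_label,
    )
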