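"""Synthetic four-sequence tumor phantoms and the fake skull shell.

The phantom stands in for skull-stripped, template-aligned glioma studies:
a smoothed ellipsoidal brain containing either a GBM-like lesion (FLAIR-
hyperintense edema enclosing an enhancing rim and a darker core on T1Gd)
or an LGG-like lesion (homogeneous, FLAIR/T2-bright, non-enhancing).  A
fake skull — a bright parabolic shell 3-10 voxels outside the brain — can
be added and removed so that acquisition artifacts see skull signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_model import (
    EmptyMaskError,
    SEQUENCE_ORDER,
    SequenceKind,
    Study,
    Volume,
    distance_outside,
)

#: Per-sequence mean intensities for (normal brain, edema, enhancing rim, core).
#: Arbitrary units with normal brain pinned at 100.  Edema is conspicuously
#: bright on FLAIR and T2W; the GBM rim enhances strongly on T1Gd; T1-weighted
#: lesions are mildly hypointense.
DEFAULT_TISSUE_TABLE: dict[SequenceKind, tuple[float, float, float, float]] = {
    SequenceKind.T1W: (100.0, 80.0, 85.0, 70.0),
    SequenceKind.T1GD: (100.0, 80.0, 220.0, 70.0),
    SequenceKind.T2W: (100.0, 180.0, 160.0, 150.0),
    SequenceKind.FLAIR: (100.0, 210.0, 190.0, 180.0),
}


class GeometryError(ValueError):
    """Raised when phantom geometry is impossible (e.g. tumor outside brain)."""


@dataclass
class PhantomParams:
    """Parameters of the synthetic study generator.

    ``brain_semiaxes`` are ellipsoid semi-axes in voxels; the tumor is a
    sphere of ``tumor_radius`` voxels at ``tumor_center`` offset (voxels)
    from the brain center.  ``noise_sd`` is the multiplicative Gaussian
    texture level as a fraction of tissue intensity.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    brain_semiaxes: tuple[float, float, float] = (30.0, 36.0, 28.0)
    tumor_center: tuple[float, float, float] = (10.0, 5.0, 4.0)
    tumor_radius: float = 12.0
    grade_label: str = "GBM-like"
    tissue_table: dict[SequenceKind, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TABLE)
    )
    noise_sd: float = 0.05
    smooth_sigma: float = 0.8
    solid_fraction: float = 0.6   # solid tumor radius / edema radius (GBM-like)
    core_fraction: float = 0.6    # core radius / solid radius (GBM-like)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grade_label not in ("GBM-like", "LGG-like"):
            raise ValueError(f"grade_label must be 'GBM-like' or 'LGG-like', got {self.grade_label!r}")
        for kind, row in self.tissue_table.items():
            if any(v <= 0 for v in row):
                raise ValueError(f"tissue intensities must be positive ({kind}: {row})")


@dataclass
class FakeSkullParams:
    """Fake-skull shell: 3-10 voxels outside the brain, parabolic intensity.

    The shell brightness peaks at ``cap_factor`` times the ``cap_percentile``-th
    percentile of each sequence's brain voxels and falls off parabolically
    toward both shell edges.
    """

    inner_offset_px: float = 3.0
    outer_offset_px: float = 10.0
    cap_factor: float = 1.2
    cap_percentile: float = 80.0
    edge_factor: float = 1.0  # multiplier of the percentile value at the shell edges

    def __post_init__(self) -> None:
        if not (0 < self.inner_offset_px < self.outer_offset_px):
            raise ValueError("require 0 < inner_offset_px < outer_offset_px")
        if self.cap_factor <= 0:
            raise ValueError("cap_factor must be positive")


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def generate_phantom(params: PhantomParams) -> Study:
    """Generate a deterministic synthetic study for the given parameters.

    The tumor mask is the union of edema and solid tumor; background is
    exactly 0; the per-sequence contrast relations of the tissue table hold
    on region means for every seed.
    """
    shape = tuple(params.grid_shape)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    brain = (
        sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, params.brain_semiaxes))
        <= 1.0
    )

    tcenter = center + np.asarray(params.tumor_center, dtype=float)
    # Tumor must sit fully inside the brain ellipsoid.
    margin = sum(
        ((tc - c) / a) ** 2 for tc, c, a in zip(tcenter, center, params.brain_semiaxes)
    )
    if margin >= 1.0 or params.tumor_radius >= (min(params.brain_semiaxes) * (1 - np.sqrt(margin))):
        raise GeometryError(
            f"tumor (radius {params.tumor_radius} at offset {params.tumor_center}) "
            "does not fit inside the brain ellipsoid"
        )

    edema = _sphere_mask(shape, tcenter, params.tumor_radius) & brain
    if params.grade_label == "GBM-like":
        solid = _sphere_mask(shape, tcenter, params.solid_fraction * params.tumor_radius) & brain
        core = _sphere_mask(shape, tcenter, params.core_fraction * params.solid_fraction * params.tumor_radius) & brain
        rim = solid & ~core
    else:
        # LGG-like: one homogeneous, diffuse, non-enhancing lesion.
        solid = np.zeros(shape, dtype=bool)
        core = np.zeros(shape, dtype=bool)
        rim = np.zeros(shape, dtype=bool)
    tumor = edema | solid

    rng = np.random.default_rng(params.rng_seed)
    sequences: dict[SequenceKind, Volume] = {}
    for kind in SEQUENCE_ORDER:
        normal, i_edema, i_rim, i_core = params.tissue_table[kind]
        img = np.zeros(shape, dtype=np.float64)
        img[brain] = normal
        img[edema] = i_edema
        if params.grade_label == "GBM-like":
            img[rim] = i_rim
            img[core] = i_core
        img *= 1.0 + params.noise_sd * rng.standard_normal(shape)
        if params.smooth_sigma > 0:
            img = ndimage.gaussian_filter(img, params.smooth_sigma)
        img[~brain] = 0.0
        # Keep intensities positive inside the brain (noise could undershoot).
        np.clip(img, 0.0, None, out=img)
        img[brain] = np.maximum(img[brain], 1e-3)
        sequences[kind] = Volume(img)

    return Study(
        subject_id=f"phantom-{params.grade_label}-{params.rng_seed}",
        sequences=sequences,
        brain_mask=brain,
        tumor_mask=tumor,
        grade_label=params.grade_label,
    )


def make_fake_skull(
    study: Study,
    params: FakeSkullParams | None = None,
    rng_seed: int = 0,
) -> tuple[Study, np.ndarray]:
    """Add a fake skull shell outside the brain; returns (study, candidate mask).

    The shell is the set of voxels whose distance to the brain lies in
    ``[inner_offset_px, outer_offset_px]``.  Within the shell each sequence
    follows a parabola in distance: ``edge_factor``×P at the shell edges
    rising to exactly ``cap_factor``×P at the apex, with P that sequence's
    ``cap_percentile``-th percentile over brain voxels.  Shell geometry is
    identical across sequences; everything outside the shell is unchanged.
    """
    del rng_seed  # the shell is deterministic; kept for interface stability
    if params is None:
        params = FakeSkullParams()
    if not study.brain_mask.any():
        raise EmptyMaskError("make_fake_skull requires a non-empty brain mask")
    dist = distance_outside(study.brain_mask)
    shell = (dist >= params.inner_offset_px) & (dist <= params.outer_offset_px)
    if not shell.any():
        warnings.warn("brain fills the grid; fake-skull shell is empty", stacklevel=2)
        return study.copy(), shell

    d = dist[shell]
    mid = 0.5 * (params.inner_offset_px + params.outer_offset_px)
    half = 0.5 * (params.outer_offset_px - params.inner_offset_px)
    # Parabola in distance: edge_factor at both edges, cap_factor at mid-shell.
    profile = params.cap_factor - (params.cap_factor - params.edge_factor) * ((d - mid) / half) ** 2
    # Discrete distances rarely hit mid exactly; rescale so the shell peak is
    # exactly cap_factor x P per sequence.
    profile = profile * (params.cap_factor / profile.max())

    out = study.copy()
    for kind, vol in out.sequences.items():
        p = np.percentile(study.volume(kind).data[study.brain_mask], params.cap_percentile)
        vol.data[shell] = profile * p
    return out, shell


def remove_fake_skull(study: Study, skull_candidate_mask: np.ndarray) -> Study:
    """Zero every voxel of the candidate shell in all sequences; masks untouched."""
    skull_candidate_mask = np.asarray(skull_candidate_mask, dtype=bool)
    if skull_candidate_mask.shape != study.shape:
        raise ValueError(
            f"skull mask shape {skull_candidate_mask.shape} != study shape {study.shape}"
        )
    out = study.copy()
    for vol in out.sequences.values():
        vol.data[skull_candidate_mask] = 0.0
    return out
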