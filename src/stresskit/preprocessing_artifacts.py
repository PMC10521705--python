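"""The three pipeline-failure artifact generators.

* Sequence mislabeling: one channel is replaced by a copy of another, as
  happens when free-text series descriptions are matched by keyword.
* Sequence misalignment: a single rigid transform applied directly to one
  channel in image space (a registration failure); the ground-truth mask
  stays put, mirroring how such a failure is scored in practice.
* Skull-stripping failure: a fraction of the fake-skull shell is left in
  place, grown from seeds near the tumor, identically in all channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .acquisition_artifacts import draw_rigid_states
from .volume_model import EmptyMaskError, SequenceKind, Study, apply_rigid

#: 26-connectivity: the fake-skull shell is thin, 6-connectivity fragments it.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MislabelSpec:
    """Which channel slot holds the wrong content, and what was copied in.

    ``replaced == substituted`` is the no-change control; the full grid is
    13 conditions (12 ordered pairs + control).
    """

    replaced: SequenceKind
    substituted: SequenceKind

    @property
    def is_control(self) -> bool:
        return self.replaced == self.substituted


def enumerate_mislabel_conditions() -> list[MislabelSpec]:
    """All 13 mislabel conditions: the no-change control then 12 ordered pairs."""
    kinds = list(SequenceKind)
    out = [MislabelSpec(SequenceKind.T1W, SequenceKind.T1W)]
    out += [MislabelSpec(r, s) for r in kinds for s in kinds if r != s]
    return out


def mislabel_sequence(study: Study, spec: MislabelSpec) -> Study:
    """Replace one channel with a bit-exact copy of another; masks untouched."""
    out = study.copy()
    out.sequences[spec.replaced] = study.volume(spec.substituted).copy()
    return out


@dataclass
class MisalignSpec:
    """Single-channel registration failure severity.

    One rigid transform is drawn uniformly within the maxima (the same
    magnitude model as the motion artifact) and applied once, in image
    space, to the target channel only.
    """

    target_sequence: SequenceKind = SequenceKind.FLAIR
    max_rot_updown_deg: float = 15.0
    max_translation_px: float = 2.0
    components: str = "both"

    def __post_init__(self) -> None:
        if self.max_rot_updown_deg < 0 or self.max_translation_px < 0:
            raise ValueError("misalignment maxima must be non-negative")

    @property
    def max_rot_leftright_deg(self) -> float:
        return self.max_rot_updown_deg / 4.0


def misalign_sequence(study: Study, spec: MisalignSpec, seed: int, return_info: bool = False):
    """Apply one random rigid transform to the target channel in image space.

    The draw matches state 1 of ``simulate_motion`` at the same seed and
    maxima (shared magnitude model).  Masks are not transformed: the
    evaluation penalizes a model against the unmoved ground truth.
    """
    rng = np.random.default_rng(seed)
    (transform,) = draw_rigid_states(
        rng, 1, spec.components, spec.max_rot_updown_deg, spec.max_translation_px
    )
    out = study.copy()
    out.sequences[spec.target_sequence] = apply_rigid(study.volume(spec.target_sequence), transform)
    if return_info:
        info = {
            "transform": {
                "rot_updown_deg": transform.rot_updown_deg,
                "rot_leftright_deg": transform.rot_leftright_deg,
                "translation_px": list(transform.translation_px),
            }
        }
        return out, info, transform
    return out


@dataclass
class SkullStripSpec:
    """Skull-strip failure severity: fraction of the fake skull left behind."""

    retained_fraction: float = 0.1
    n_seeds_near_tumor: int = 3
    tumor_proximity_px: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.retained_fraction <= 1.0):
            raise ValueError(f"retained_fraction must be in [0, 1], got {self.retained_fraction}")


#: The severity grid used in the experiments.
SKULL_STRIP_FRACTIONS = (0.0, 0.01, 0.02, 0.05, 0.10, 0.25, 0.50, 1.00)


def _growth_order(
    candidate: np.ndarray,
    tumor_mask: np.ndarray,
    spec: SkullStripSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic retention order of candidate voxels and the seed coords.

    Voxels are ranked by (region-growing layer from the seeds over the
    shell's 26-connected adjacency, Euclidean distance to the nearest
    seed, lexicographic index); unreachable shell components come last.
    The order is independent of the retained fraction, so retained sets
    are nested across fractions at a fixed seed.
    """
    coords = np.argwhere(candidate)
    dist_tumor = ndimage.distance_transform_edt(~tumor_mask)
    near = coords[dist_tumor[tuple(coords.T)] <= spec.tumor_proximity_px]
    if len(near) == 0:
        # No shell voxel within proximity: fall back to the nearest ones.
        order = np.argsort(dist_tumor[tuple(coords.T)], kind="stable")
        near = coords[order[: spec.n_seeds_near_tumor]]
        seeds = near
    else:
        k = min(spec.n_seeds_near_tumor, len(near))
        seeds = near[rng.choice(len(near), size=k, replace=False)]

    # Multi-source region growing: layer = number of 26-connected dilation
    # steps from the seed set, restricted to the shell.
    layer = np.full(candidate.shape, np.inf)
    reached = np.zeros(candidate.shape, dtype=bool)
    reached[tuple(seeds.T)] = True
    layer[reached] = 0
    step = 0
    while True:
        step += 1
        new = ndimage.binary_dilation(reached, _STRUCT_26) & candidate & ~reached
        if not new.any():
            break
        layer[new] = step
        reached |= new

    d2seed = np.min(
        ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2), axis=1
    ).astype(float)
    flat = np.ravel_multi_index(tuple(coords.T), candidate.shape)
    order = np.lexsort((flat, np.sqrt(d2seed), layer[tuple(coords.T)]))
    return coords[order], seeds


def fail_skull_strip(
    study: Study,
    skull_candidate_mask: np.ndarray,
    spec: SkullStripSpec,
    seed: int,
    return_info: bool = False,
):
    """Strip all but a retained fraction of the fake-skull shell.

    ``study`` must carry the fake skull; exactly ``round(p * |candidate|)``
    voxels (round-half-to-even) keep their skull intensities in all four
    sequences, grown from seeds near the tumor; the rest are set to 0.
    Retained sets are nested across fractions at a fixed seed.
    """
    candidate = np.asarray(skull_candidate_mask, dtype=bool)
    if candidate.shape != study.shape:
        raise ValueError("skull candidate mask is on a different grid")
    if not candidate.any():
        raise EmptyMaskError("empty skull candidate mask")

    n_candidate = int(np.count_nonzero(candidate))
    n_target = int(np.round(spec.retained_fraction * n_candidate))
    rng = np.random.default_rng(seed)
    ordered, seeds = _growth_order(candidate, study.tumor_mask, spec, rng)
    retained = np.zeros(study.shape, dtype=bool)
    if n_target > 0:
        retained[tuple(ordered[:n_target].T)] = True

    out = study.copy()
    stripped = candidate & ~retained
    for vol in out.sequences.values():
        vol.data[stripped] = 0.0
    if return_info:
        info = {
            "seeds": seeds.tolist(),
            "n_candidate": n_candidate,
            "n_retained": int(np.count_nonzero(retained)),
        }
        return out, retained, info
    return out
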