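"""The four acquisition-physics artifact generators.

* Motion: the head occupies several positions during the scan; k-space
  segments acquired at different times come from differently-posed copies
  of the volume, producing ghosting along the phase-encoding axis.
* Susceptibility signal loss: a roughly spherical dark void outside the
  brain near the tumor, smaller on T1-weighted sequences.
* Aliasing: a too-small field of view folds ghost copies of the volume
  back along the phase axis, modelled by comb undersampling of k-space.
* Field inhomogeneity: a smooth multiplicative bias field built from
  Gaussians seeded near the brain surface (surface receiver coils).

All generators are deterministic given a seed, and the random *shape* of
an artifact (directions, seed locations) depends only on the seed, never
on the severity level, so severity sweeps vary one thing at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kspace import KSpace, comb_undersample, from_kspace, segment_phase_encodes, to_kspace
from .volume_model import (
    EmptyMaskError,
    RigidTransform,
    SequenceKind,
    Study,
    apply_rigid,
)


class PlacementError(RuntimeError):
    """Raised when no admissible artifact location exists on the grid."""


# ---------------------------------------------------------------------------
# Specs


@dataclass
class MotionSpec:
    """Motion severity and scope.

    The chin-up/down (X-axis) rotation maximum is four times the
    head-left/right (Z-axis) maximum because the head is freer to nod in
    the coil.  Per-state magnitudes are drawn uniformly on [-max, +max]
    per component; translations are drawn independently per axis.
    """

    target_sequence: SequenceKind = SequenceKind.FLAIR
    mode: str = "3D"  # "3D" or "2D" reconstruction
    components: str = "both"  # "rotation", "translation", or "both"
    max_rot_updown_deg: float = 15.0
    max_translation_px: float = 2.0
    n_states: int = 10

    def __post_init__(self) -> None:
        if self.components not in ("rotation", "translation", "both"):
            raise ValueError(f"components must be rotation|translation|both, got {self.components!r}")
        if self.max_rot_updown_deg < 0 or self.max_translation_px < 0:
            raise ValueError("motion maxima must be non-negative")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if 0 < self.max_rot_updown_deg and not (3.75 <= self.max_rot_updown_deg <= 45):
            warnings.warn(
                f"max_rot_updown_deg={self.max_rot_updown_deg} outside the usual 3.75-45 range",
                stacklevel=2,
            )
        if 0 < self.max_translation_px and not (0.5 <= self.max_translation_px <= 6):
            warnings.warn(
                f"max_translation_px={self.max_translation_px} outside the usual 0.5-6 range",
                stacklevel=2,
            )

    @property
    def max_rot_leftright_deg(self) -> float:
        return self.max_rot_updown_deg / 4.0


@dataclass
class SusceptibilitySpec:
    """Susceptibility signal-loss severity.

    ``base_radius_px`` is the nominal void radius on T2W/FLAIR; T1W/T1Gd
    use ``t1_radius_factor`` times that radius around the same center (T2-
    weighted sequences are more sensitive to local field changes).  The
    void is made irregular by adding/subtracting smaller spheres and
    smooth noise; its boundary is dimmed in a linear gradient over
    ``boundary_width_px`` rather than cut to background.
    """

    base_radius_px: float = 20.0
    boundary_width_px: float = 10.0
    t1_radius_factor: float = 0.2
    n_perturb_spheres: int = 6
    perturb_radius_fraction: float = 0.3
    noise_amplitude: float = 0.1
    placement_margin_px: float = 5.0
    max_tries: int = 1000

    def __post_init__(self) -> None:
        if self.base_radius_px <= 0:
            raise ValueError("base_radius_px must be positive")
        if not (0 < self.t1_radius_factor <= 1):
            raise ValueError("t1_radius_factor must be in (0, 1]")
        if not (5 <= self.base_radius_px <= 50):
            warnings.warn(
                f"base_radius_px={self.base_radius_px} outside the usual 5-50 range",
                stacklevel=2,
            )

    @property
    def reach_radius_px(self) -> float:
        """Maximum core extent from the center (base + perturbing spheres)."""
        return self.base_radius_px * (1.0 + self.perturb_radius_fraction)


@dataclass
class AliasSpec:
    """Aliasing severity: number of ghost copies folded along the phase axis."""

    n_aliases: int = 2
    target_sequence: SequenceKind = SequenceKind.FLAIR

    def __post_init__(self) -> None:
        if not float(self.n_aliases).is_integer() or self.n_aliases < 1:
            raise ValueError(f"n_aliases must be an integer >= 1, got {self.n_aliases!r}")
        self.n_aliases = int(self.n_aliases)
        if self.n_aliases > 8:
            warnings.warn(f"n_aliases={self.n_aliases} outside the usual 1-8 range", stacklevel=2)


@dataclass
class InhomogeneitySpec:
    """Bias-field severity: multiplicative gains bounded by [gain_low, gain_high].

    Five Gaussian high points (sd ``sigma_px``) are seeded near the brain
    edge; their upper envelope is rescaled over the brain so the field
    attains exactly ``gain_high`` at its brightest point and ``gain_low``
    at its darkest.
    """

    gain_high: float = 1.25
    gain_low: float = 0.75
    n_seeds: int = 5
    sigma_px: float = 75.0
    edge_band_px: float = 5.0

    def __post_init__(self) -> None:
        if not (self.gain_low <= 1.0 <= self.gain_high):
            raise ValueError("require gain_low <= 1 <= gain_high")
        if self.gain_high != 1.0 and not (1.05 <= self.gain_high <= 1.4):
            warnings.warn(f"gain_high={self.gain_high} outside the usual 1.05-1.4 range", stacklevel=2)
        if self.gain_low != 1.0 and not (0.6 <= self.gain_low <= 0.95):
            warnings.warn(f"gain_low={self.gain_low} outside the usual 0.6-0.95 range", stacklevel=2)


# ---------------------------------------------------------------------------
# Shared rigid-state sampling (used by motion and by misalignment)


def draw_rigid_states(
    rng: np.random.Generator,
    n: int,
    components: str,
    max_rot_updown_deg: float,
    max_translation_px: float,
    interpolation: str = "linear",
) -> list[RigidTransform]:
    """Draw ``n`` random rigid states, uniform per component within the maxima.

    Unit draws on [-1, 1] are scaled by the maxima, so at a fixed seed the
    *directions* of motion are identical across a severity sweep and the
    magnitudes scale linearly.  Draw order is fixed regardless of
    ``components`` so that rotation-only / translation-only / both runs
    share the same underlying randomness.
    """
    transforms, _units = _draw_rigid_states_with_units(
        rng, n, components, max_rot_updown_deg, max_translation_px, interpolation
    )
    return transforms


def _draw_rigid_states_with_units(
    rng: np.random.Generator,
    n: int,
    components: str,
    max_rot_updown_deg: float,
    max_translation_px: float,
    interpolation: str = "linear",
) -> tuple[list[RigidTransform], list[np.ndarray]]:
    """As :func:`draw_rigid_states`, also returning the raw unit draws.

    The unit draws (u_rot_ud, u_rot_lr, u_tx, u_ty, u_tz on [-1, 1], with
    disabled components zeroed) describe the severity-independent *shape*
    of the motion; they are what a sweep logs as geometry.
    """
    max_lr = max_rot_updown_deg / 4.0
    rot_on = components in ("rotation", "both")
    tr_on = components in ("translation", "both")
    transforms: list[RigidTransform] = []
    units: list[np.ndarray] = []
    for _ in range(n):
        u = rng.uniform(-1.0, 1.0, size=5)
        masked = u * np.array([rot_on, rot_on, tr_on, tr_on, tr_on], dtype=float)
        units.append(masked)
        transforms.append(
            RigidTransform(
                rot_updown_deg=masked[0] * max_rot_updown_deg,
                rot_leftright_deg=masked[1] * max_lr,
                translation_px=tuple(masked[2:5] * max_translation_px),
                interpolation=interpolation,
            )
        )
    return transforms, units


# ---------------------------------------------------------------------------
# Motion


def simulate_motion(
    study: Study,
    spec: MotionSpec,
    seed: int,
    forced_transforms: list[RigidTransform] | None = None,
    return_info: bool = False,
):
    """Corrupt one sequence with k-space segmented motion.

    The volume is posed in ``n_states`` positions (state 0 = unmoved
    reference); each pose is Fourier transformed (3D, or slicewise 2D) and
    the Cartesian phase-encode order is split into contiguous temporal
    segments, one per state, with the central segment taken from the
    reference.  The spliced k-space is inverse transformed and the
    magnitude kept.  Only the target sequence is modified.

    ``forced_transforms`` overrides the random states (testing hook).
    """
    vol = study.volume(spec.target_sequence)
    rng = np.random.default_rng(seed)
    if forced_transforms is not None:
        transforms = list(forced_transforms)
        if len(transforms) != spec.n_states - 1:
            raise ValueError(f"need {spec.n_states - 1} forced transforms, got {len(transforms)}")
        units = [
            np.array([t.rot_updown_deg, t.rot_leftright_deg, *t.translation_px])
            for t in transforms
        ]
    else:
        transforms, units = _draw_rigid_states_with_units(
            rng, spec.n_states - 1, spec.components,
            spec.max_rot_updown_deg, spec.max_translation_px,
        )
    segments = segment_phase_encodes(vol.shape, spec.n_states, spec.mode)
    k = to_kspace(vol, spec.mode).data.copy()
    for state, transform in enumerate(transforms, start=1):
        moved = vol if transform.is_identity else apply_rigid(vol, transform)
        ks = to_kspace(moved, spec.mode).data
        mask = segments.state_mask(state)
        k[mask] = ks[mask]
    corrupted = from_kspace(
        KSpace(k, spec.mode, spacing=tuple(vol.spacing)), magnitude=True
    )
    out = study.copy()
    out.sequences[spec.target_sequence] = corrupted
    if return_info:
        info = {
            "transforms": [
                {
                    "rot_updown_deg": t.rot_updown_deg,
                    "rot_leftright_deg": t.rot_leftright_deg,
                    "translation_px": list(t.translation_px),
                }
                for t in transforms
            ],
            # severity-independent shape of the motion (raw unit draws)
            "directions": [u.tolist() for u in units],
        }
        return out, info
    return out


# ---------------------------------------------------------------------------
# Susceptibility signal loss


def _tumor_centroid_and_radius(tumor_mask: np.ndarray) -> tuple[np.ndarray, float]:
    coords = np.argwhere(tumor_mask)
    centroid = coords.mean(axis=0)
    radius = float(np.sqrt(((coords - centroid) ** 2).sum(axis=1).max()))
    return centroid, radius


def simulate_signal_loss(
    study: Study,
    spec: SusceptibilitySpec,
    seed: int,
    return_info: bool = False,
):
    """Apply a susceptibility-like signal void shared across all sequences.

    One center is sampled outside the brain, near but not overlapping the
    tumor: the center sits on a seed-determined ray from the tumor
    centroid at a distance slightly larger than the artifact's effective
    radius, so the void abuts the tumor without touching it.  T2W/FLAIR
    use the base radius; T1W/T1Gd a radius scaled by ``t1_radius_factor``
    about the same center.  Intensities inside the irregular core go to 0;
    a linear gradient over ``boundary_width_px`` ramps the attenuation
    back to none.  Every modified voxel satisfies output <= input.
    """
    if not study.tumor_mask.any():
        raise EmptyMaskError("signal loss requires a non-empty tumor mask")
    if study.brain_mask.all():
        raise PlacementError("no exterior voxels: brain fills the grid")

    shape = study.shape
    rng = np.random.default_rng(seed)
    # Fixed draw order so artifact geometry is seed-determined and identical
    # across severity levels: directions, margin, perturbations, noise.
    dirs = rng.standard_normal((spec.max_tries, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    margin = rng.uniform(0.0, spec.placement_margin_px)
    offs = rng.standard_normal((spec.n_perturb_spheres, 3))
    offs /= np.linalg.norm(offs, axis=1, keepdims=True)
    offs *= rng.uniform(0.0, 1.0, size=(spec.n_perturb_spheres, 1)) ** (1.0 / 3.0)
    signs = rng.choice([-1.0, 1.0], size=spec.n_perturb_spheres)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    noise /= noise.std()

    centroid, tumor_radius = _tumor_centroid_and_radius(study.tumor_mask)
    r_eff = spec.reach_radius_px + spec.boundary_width_px
    dist_to_tumor = ndimage.distance_transform_edt(~study.tumor_mask)

    center = None
    direction = None
    for d in dirs:
        t = tumor_radius + r_eff + margin
        diag = float(np.linalg.norm(shape))
        while t <= diag:
            cand = np.round(centroid + t * d).astype(int)
            if np.any(cand < 0) or np.any(cand >= np.asarray(shape)):
                break
            if (not study.brain_mask[tuple(cand)]) and dist_to_tumor[tuple(cand)] > r_eff:
                center = cand
                direction = d
                break
            t += 1.0
        if center is not None:
            break
    if center is None:
        raise PlacementError(
            f"no admissible signal-loss center for base_radius={spec.base_radius_px} "
            f"within {spec.max_tries} candidate directions"
        )

    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d0 = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center.astype(float))))

    out = study.copy()
    groups = [
        (spec.base_radius_px, (SequenceKind.T2W, SequenceKind.FLAIR)),
        (spec.t1_radius_factor * spec.base_radius_px, (SequenceKind.T1W, SequenceKind.T1GD)),
    ]
    counts: dict[str, int] = {}
    for radius, kinds in groups:
        field = radius - d0
        for off, sgn in zip(offs, signs):
            ci = center + off * radius
            di = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, ci)))
            field = field + sgn * np.maximum(0.0, spec.perturb_radius_fraction * radius - di)
        field = field + spec.noise_amplitude * radius * noise
        core = (field > 0) & (d0 <= radius * (1.0 + spec.perturb_radius_fraction))
        if core.any():
            ramp = ndimage.distance_transform_edt(~core)
            atten = np.clip(ramp / spec.boundary_width_px, 0.0, 1.0)
        else:
            atten = np.ones(shape)
        for kind in kinds:
            out.sequences[kind].data *= atten
            counts[kind.value] = int(np.count_nonzero(atten < 1.0))
    if return_info:
        info = {
            "center": center.tolist(),
            "direction": direction.tolist(),
            "margin": float(margin),
            "affected_counts": counts,
        }
        return out, info
    return out


# ---------------------------------------------------------------------------
# Aliasing


def simulate_aliasing(study: Study, spec: AliasSpec, return_info: bool = False):
    """Fold ``n_aliases`` ghost copies of one sequence along the phase axis.

    Implemented as comb undersampling with factor R = n_aliases + 1
    followed by magnitude inverse transform: the result superposes R
    copies shifted by multiples of L/R along the phase-encoding axis.
    Deterministic; only the target sequence is modified.
    """
    vol = study.volume(spec.target_sequence)
    ksp = to_kspace(vol, "3D")
    ksp = comb_undersample(ksp, spec.n_aliases + 1)
    out = study.copy()
    out.sequences[spec.target_sequence] = from_kspace(ksp, magnitude=True)
    if return_info:
        return out, {"n_aliases": spec.n_aliases}
    return out


# ---------------------------------------------------------------------------
# Field inhomogeneity


def simulate_inhomogeneity(
    study: Study,
    spec: InhomogeneitySpec,
    seed: int,
    return_info: bool = False,
):
    """Multiply all sequences by one smooth bias field; returns (study, bias).

    ``n_seeds`` high points are sampled from the band of brain voxels
    within ``edge_band_px`` of the brain surface.  The upper envelope of
    the per-seed Gaussians (sd ``sigma_px``) is affinely rescaled over the
    brain to [0, 1], then mapped to [gain_low, gain_high]; the field
    therefore attains exactly both gains over the brain, peaking at the
    best seed.  The field geometry depends only on the seed locations, so
    a gain sweep at fixed seed rescales one fixed field.
    """
    if not study.brain_mask.any():
        raise EmptyMaskError("inhomogeneity requires a non-empty brain mask")
    inside = ndimage.distance_transform_edt(study.brain_mask)
    band = study.brain_mask & (inside <= spec.edge_band_px)
    if not band.any():
        raise EmptyMaskError("empty brain-edge band for inhomogeneity seeds")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(band)
    picks = coords[rng.choice(len(coords), size=spec.n_seeds, replace=False)]

    shape = study.shape
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    envelope = np.zeros(shape)
    for s in picks:
        d2 = sum((g - c) ** 2 for g, c in zip(grids, s.astype(float)))
        np.maximum(envelope, np.exp(-d2 / (2.0 * spec.sigma_px**2)), out=envelope)
    lo = envelope[study.brain_mask].min()
    hi = envelope[study.brain_mask].max()
    if hi > lo:
        # clip: voxels outside the brain may fall below the brain minimum
        norm = np.clip((envelope - lo) / (hi - lo), 0.0, 1.0)
    else:  # degenerate: single flat field
        norm = np.ones(shape)
    bias = spec.gain_low + (spec.gain_high - spec.gain_low) * norm

    out = study.copy()
    for vol in out.sequences.values():
        vol.data *= bias
    if return_info:
        return out, bias, {"seeds": picks.tolist()}
    return out, bias
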