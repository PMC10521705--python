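"""Frequency-domain machinery: FFTs, Cartesian acquisition order, comb undersampling.

MRI data are acquired in k-space along a Cartesian trajectory.  By default
the phase-encoding axis is X (left-right, the short axis of the head), the
frequency-encoding axis is Y (anterior-posterior), and Z is the slice axis
(2D mode) or second phase-encoding axis (3D mode).  All transforms are
orthonormal, so Parseval's identity holds and round trips are exact to
floating precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_model import Volume


@dataclass
class KSpace:
    """Complex k-space data for one volume plus its encoding conventions."""

    data: np.ndarray
    mode: str = "3D"  # "3D" or "2D"
    phase_axis: int = 0
    frequency_axis: int = 1
    slice_axis: int = 2
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.mode not in ("3D", "2D"):
            raise ValueError(f"mode must be '3D' or '2D', got {self.mode!r}")
        axes = {self.phase_axis, self.frequency_axis, self.slice_axis}
        if axes != {0, 1, 2}:
            raise ValueError("phase/frequency/slice axes must be a permutation of (0,1,2)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "KSpace":
        return KSpace(
            self.data.copy(), self.mode, self.phase_axis, self.frequency_axis,
            self.slice_axis, tuple(self.spacing),
        )


def to_kspace(
    volume: Volume,
    mode: str = "3D",
    phase_axis: int = 0,
    frequency_axis: int = 1,
) -> KSpace:
    """Forward orthonormal FFT of a volume.

    3D mode transforms all three axes at once; 2D mode transforms each slice
    (plane orthogonal to the slice axis) independently, as in slicewise
    acquisition.
    """
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("to_kspace requires finite input")
    slice_axis = ({0, 1, 2} - {phase_axis, frequency_axis}).pop()
    if mode == "3D":
        data = np.fft.fftn(volume.data, norm="ortho")
    elif mode == "2D":
        data = np.fft.fftn(volume.data, axes=(phase_axis, frequency_axis), norm="ortho")
    else:
        raise ValueError(f"mode must be '3D' or '2D', got {mode!r}")
    return KSpace(data, mode, phase_axis, frequency_axis, slice_axis, tuple(volume.spacing))


def from_kspace(kspace: KSpace, magnitude: bool = False) -> Volume:
    """Inverse orthonormal FFT.

    With ``magnitude=True`` returns ``|ifft|`` as in MRI magnitude
    reconstruction; otherwise the real part (imaginary parts of an
    unmodified k-space are at floating-noise level).
    """
    if kspace.mode == "3D":
        img = np.fft.ifftn(kspace.data, norm="ortho")
    else:
        img = np.fft.ifftn(
            kspace.data, axes=(kspace.phase_axis, kspace.frequency_axis), norm="ortho"
        )
    out = np.abs(img) if magnitude else img.real
    return Volume(out, tuple(kspace.spacing))


@dataclass
class AcquisitionSegments:
    """Contiguous temporal segments of the Cartesian phase-encode order.

    ``assignment[i]`` is the motion-state id of the i-th phase-encode index
    in acquisition order.  Segments partition the indices into ``n_states``
    contiguous blocks whose sizes differ by at most one; the block containing
    the central index is state 0 (the motion-free reference), so the k-space
    center is always acquired without motion.

    In 2D mode the phase-encode indices are the X lines of one slice (the
    same segmentation applies to every slice); in 3D mode they are all
    (Z plane, X line) pairs in lexicographic acquisition order.
    """

    n_states: int
    assignment: np.ndarray
    mode: str
    shape: tuple[int, int, int]
    phase_axis: int = 0
    slice_axis: int = 2

    def state_mask(self, state: int) -> np.ndarray:
        """Boolean k-space mask (full 3D) selecting the samples of one state."""
        nx = self.shape[self.phase_axis]
        if self.mode == "2D":
            mask = np.zeros(self.shape, dtype=bool)
            lines = np.nonzero(self.assignment == state)[0]
            idx: list[slice | np.ndarray] = [slice(None)] * 3
            idx[self.phase_axis] = lines
            mask[tuple(idx)] = True
            return mask
        nz = self.shape[self.slice_axis]
        grid = self.assignment.reshape(nz, nx) == state  # (z, x) lexicographic
        shape1 = [1, 1, 1]
        shape1[self.phase_axis] = nx
        shape1[self.slice_axis] = nz
        if self.phase_axis < self.slice_axis:
            grid = grid.T  # axis order (x, z) to match the 3D layout
        return np.broadcast_to(grid.reshape(shape1), self.shape).copy()


def segment_phase_encodes(
    shape: tuple[int, int, int],
    n_states: int = 10,
    mode: str = "3D",
    phase_axis: int = 0,
    slice_axis: int = 2,
) -> AcquisitionSegments:
    """Partition the phase-encode acquisition order into contiguous state blocks."""
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    nx = shape[phase_axis]
    n_lines = nx if mode == "2D" else nx * shape[slice_axis]
    if n_states > n_lines:
        raise ValueError(f"n_states={n_states} exceeds {n_lines} phase-encode lines")
    # Contiguous blocks with sizes differing by <= 1 (np.array_split layout).
    bounds = np.linspace(0, n_lines, n_states + 1).astype(int)
    block_of_line = np.searchsorted(bounds, np.arange(n_lines), side="right") - 1
    central_block = int(block_of_line[n_lines // 2])
    # Relabel so that the central block is state 0; blocks keep acquisition order.
    assignment = (block_of_line - central_block) % n_states
    return AcquisitionSegments(n_states, assignment, mode, tuple(shape), phase_axis, slice_axis)


def comb_undersample(kspace: KSpace, factor_R: int) -> KSpace:
    """Keep every R-th phase-encode line (from line 0), zero the rest, scale by R.

    By the Fourier comb theorem the inverse transform is the superposition of
    R copies of the image shifted by multiples of L/R along the phase axis
    (for L divisible by R), which is exactly the wraparound/ghosting
    appearance of aliasing.  R=1 is the identity.
    """
    if not float(factor_R).is_integer() or factor_R < 1:
        raise ValueError(f"factor_R must be an integer >= 1, got {factor_R!r}")
    factor_R = int(factor_R)
    out = kspace.copy()
    if factor_R == 1:
        return out
    keep: list[slice] = [slice(None)] * 3
    keep[kspace.phase_axis] = slice(0, None, factor_R)
    new = np.zeros_like(out.data)
    new[tuple(keep)] = out.data[tuple(keep)] * factor_R
    out.data = new
    return out
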