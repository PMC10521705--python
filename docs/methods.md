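# Methods

This note documents the models behind each simulated artifact, the phantom
the toolkit ships for data-free testing, the numerical choices made where
the design was genuinely open, and what the passing test suite does and
does not establish about real data.

## Data model and conventions

A *study* is four co-registered 3D sequences (T1W, T1Gd, T2W, FLAIR) plus a
brain mask and a tumor mask on one isotropic grid (1 voxel ≡ 1 mm).
Voxel indices are 0-based with axis order (X, Y, Z) = (left–right,
anterior–posterior, inferior–superior). Studies are assumed skull-stripped
with exactly-zero background; the brain mask is the largest connected
component of positive intensity. Rigid transforms rotate about the grid
center — the only symmetric choice when motion axes are defined
anatomically — with chin-up/down as rotation about X and head-left/right as
rotation about Z, composed chin-first; out-of-field voxels are filled with
the zero background. Residual scaling between template voxels and scanner
millimetres in real data is not modelled.

## Phantom

The phantom is the minimal structure that exercises every artifact and a
contrast-driven segmenter: a smoothed ellipsoidal brain (default semi-axes
30 × 36 × 28 voxels on a 96³ grid, leaving the ≥10-voxel exterior band the
fake skull needs), a spherical lesion, per-sequence mean intensities from a
tissue table (normal brain pinned at 100), multiplicative Gaussian noise
(sd 5 % of tissue intensity) and a light Gaussian smoothing (σ = 0.8 voxel)
for texture. GBM-like lesions are edema (FLAIR 210, i.e. conspicuously
hyperintense) enclosing a solid tumor whose rim enhances on T1Gd (220 vs
100); LGG-like lesions are homogeneous, FLAIR/T2-bright and non-enhancing.
The tumor mask is edema ∪ solid. These contrast relations hold on region
means for every seed (property-tested over 100 seeds).

What the phantom does *not* emulate: anatomical structure (ventricles, gray/
white matter), infiltrative lesion margins, scanner noise statistics
(Rician), partial-volume effects, or inter-subject anatomical variability.
Passing sweeps therefore demonstrate the *mechanics* of each artifact and
the direction of its effect on a contrast-driven segmenter, not the
magnitude of degradation any trained model would show on clinical data.

## Fake skull

Real artifacts interact with the bright skull, which skull-stripped archives
lack. The shell is the set of voxels whose Euclidean distance to the brain
lies in [3, 10] voxels. Within it, each sequence follows a parabola in
distance: 1.0 × P80 at both shell edges rising to 1.2 × P80 at the apex,
where P80 is that sequence's 80th-percentile brain intensity. The apex is
placed at mid-shell (distance 6.5) — the least-assuming reading of a
"parabolic, decreasing slightly" profile — and, because discrete distances
rarely hit 6.5 exactly, the profile is rescaled so the realized shell
maximum equals 1.2 × P80 exactly per sequence. Shell geometry is identical
across sequences; only the cap differs. The shell is a deliberately crude
skull: no ocular cavity, mandible, or tissue layering.

## Motion

Cartesian acquisition with phase encoding along X and frequency encoding
along Y (the common head-MRI setting; both configurable). The phase-encode
order — X lines per slice in 2D mode, (Z plane, X line) pairs in
lexicographic order in 3D mode — is partitioned into `n_states = 10`
contiguous temporal segments of near-equal size. State 0 is the unmoved
reference and is assigned to the segment containing the central phase-encode
index, so the k-space center (gross contrast) is acquired motion-free, the
null-motion limit is continuous, and ghosting appears peripherally. Which
k-space samples belong to which head position is not otherwise constrained
by the physics; the contiguous-block scheme is the canonical line-sequential
choice and is documented as such.

Each of the 9 moving states draws per-component magnitudes uniformly on
[−max, +max]: chin rotation up to `max_rot_updown_deg`, head rotation up to
a quarter of that (the head is freer to nod), and translations drawn
independently per axis. The draws are stored as unit values on [−1, 1] and
scaled by the maxima, so at a fixed seed the *directions* of motion are
identical across a severity sweep. All transforms use the orthonormal FFT
pair; the output is the magnitude of the inverse transform, as in MRI
magnitude reconstruction (splicing leaves small imaginary parts). The
severity presets scale rotation 3.75°→45° and translation 0.5→6 px over 12
factors; an alternative millimetre-scale translation grid (1–12 mm) exists
in the literature for the same experiment and can be set directly through
`max_translation_px`. Even/odd-slice interleaved motion is out of scope.

## Susceptibility signal loss

A roughly spherical void, physically present in all sequences at one shared
center, with radius 80 % smaller (linear radius × 0.2 — the simplest
reading) on T1W/T1Gd. The base sphere is made organic by six smaller
spheres (radius 0.3 × base, centers inside the base ball) added or
subtracted, plus smooth Gaussian noise (amplitude 0.1 × radius, σ = 2 vox);
the core is clipped to a ball of radius 1.3 × base so its maximal reach is
known. Core intensities are multiplied by 0; a linear ramp over the
10-voxel boundary restores attenuation to none, so every modified voxel
satisfies output ≤ input. Bright pile-up and geometric distortion are not
simulated.

Placement must be outside the brain, near the tumor, at a distance slightly
larger than the artifact's effective radius (core reach + boundary), so the
void abuts but never overlaps the tumor. Because that distance necessarily
grows with radius, a radius sweep cannot keep the center literally fixed;
what is held fixed at a given seed is the *geometry* of the draw: the
direction of the placement ray from the tumor centroid, the margin, and the
perturbation offsets/signs. The center is the first voxel along the first
feasible ray (from a seed-fixed candidate list) that satisfies the
constraints; radii too large for the grid raise a placement error, which
the sweep records as a flagged condition. On the 96³ default phantom this
occurs at the top of the 5–50 px radius grid — those radii were designed
for full-size template grids.

## Aliasing

Keeping every R-th phase-encode line (from line 0), zeroing the rest and
multiplying retained lines by R is exactly the Fourier comb: the inverse
transform superposes R copies of the image shifted by multiples of L/R
along the phase axis, reproducing wraparound/parallel-imaging ghosts with
`n_aliases = R − 1` extra copies. The factor-R intensity scaling keeps the
summed copies on the original intensity scale. Deterministic; applied to
one sequence at a time. Non-Cartesian trajectories and coil-sensitivity
models are out of scope.

## Field inhomogeneity

Five seed voxels are sampled from the band of brain voxels within 5 voxels
of the brain surface ("near the surface receiver coils"; the band width is
a documented reading of "near the edge"). Each seed contributes a spherical
Gaussian of σ = 75 voxels in Euclidean distance; the field is their upper
envelope — the seeds are high points, and the max combination plus an affine
rescale over the brain guarantees the stated extremes exactly: the bias
attains `gain_high` (default 1.25) at the best seed and `gain_low` (default
0.75) at the darkest brain voxel. Outside the brain the normalized field is
clipped to [0, 1] so the bias never leaves [gain_low, gain_high]. One field
multiplies all four sequences. A gain sweep at fixed seed rescales one
fixed geometry.

## Preprocessing artifacts

*Mislabeling* copies one channel over another, bit-exactly; the 13
conditions are the 12 ordered pairs plus the no-change control.

*Misalignment* draws one rigid transform with the same magnitude model as
motion (it reproduces motion state 1 at equal seed and maxima) and applies
it once, in image space, to one channel. Masks are not transformed: the
experiment measures a model against the fixed ground truth, as a real
pipeline would score it — a radiologist would notice the misalignment, the
model cannot.

*Skull-strip failure* retains exactly `round(p·|shell|)` voxels
(round-half-to-even for cross-platform determinism) of the fake-skull
shell, identically in all sequences. Three seeds are sampled from shell
voxels within 15 voxels of the tumor (skull-strippers typically fail near
bright tumor; if no shell voxel is that close, the nearest ones are used)
and the retained region grows over the shell's 26-connected adjacency
(6-connectivity fragments the thin shell), ranked by growth layer, then
distance to the nearest seed, then lexicographic index. Ranking once and
taking prefixes makes retained sets nested across fractions at fixed seed.
Removing tumor mistaken for skull is deliberately not simulated.

## Harness

Artifact randomness is seeded by a BLAKE2b hash (version-pinned, 8-byte
digest, pinned in a test) of "subject␟artifact␟sequence" — severity is
excluded so artifact shape is constant within a subject across a sweep.
The pipeline per condition is: add fake skull → apply artifact → remove
fake skull (skull-strip failure replaces the removal step) → segment →
score against the *unmodified* tumor mask. Per-sequence artifacts (motion,
aliasing, misalignment) iterate over all four sequences; whole-study
artifacts produce one condition per level. Severity grids: motion/misalign
factors 1–12; signal-loss radius 5–50 step 5; aliases 1–8; gain pairs
(1.05, 0.95)–(1.40, 0.60) step 0.05; 13 mislabel conditions; skull
fractions {0, .01, .02, .05, .10, .25, .50, 1}. The mislabel and
skull-strip grids contain their own control condition; for the other
artifacts an explicit no-artifact control row is available via
`include_control`. Records are written as RFC-4180 CSV with a stable
column order and 10-significant-digit floats, so identical runs are
byte-identical. A failing condition (e.g. an infeasible signal-loss
placement) is flagged and the sweep continues.

Metrics: Dice (defined as 1.0 when both masks are empty), sensitivity and
specificity (NaN with a flag when a class is empty), rank-based AUROC with
midranks for ties, and raw confusion counts. The one-way repeated-measures
ANOVA partitions sums of squares definitionally (treatment, subject,
error); F = MS_treatment/MS_error with df (k−1) and (k−1)(n−1), p from the
F distribution, significance flagged at p < 0.01, raw p-values with no
multiplicity correction and no sphericity correction. Treatment and
subject sums of squares are centered on the mean of their own means so the
all-columns-identical case yields exactly F = 0. The implementation is
cross-checked in the tests against the paired-t identity (k = 2) and
statsmodels' AnovaRM.

The *baseline segmenter* — min-max-normalized FLAIR thresholded by Otsu
within the brain, opened with a radius-1 ball, largest component kept — is
a transparent stand-in for a trained model. It reads only the FLAIR slot,
which makes direction-of-effect experiments interpretable (FLAIR
mislabeling is catastrophic; bias fields and FLAIR-targeted artifacts
degrade it; T1-slot artifacts do not), but it is *not* a claim about any
particular network's sensitivities.

## Problem sizes and determinism

The shipped experiments run at desk scale: 96³ phantoms, cohorts of 10
(5 GBM-like, 5 LGG-like), full inhomogeneity and mislabel grids — chosen so
the complete suite and the acceptance script each run in minutes on one
CPU while still exercising every code path at the experiment's native
design (record counts 10 × 8 and 10 × 13). Unit tests use 64³ phantoms and
16³ Fourier oracles. All randomness flows through `numpy.random.default_rng`
from explicit seeds; there is no global RNG state.

## Known limitations

- Dice scores from the bundled phantom + baseline segmenter are not
  comparable in magnitude to any trained model's scores on clinical data;
  only directions and mechanics transfer.
- The signal-loss placement rule makes the largest radii infeasible on
  small grids (flagged, not silently skipped).
- The fake skull is a single bright shell, not layered anatomy; skull-strip
  failure effects are correspondingly mild.
- Misalignment's angle-form inverse exists only for single-axis rotations
  or pure translations; the general inverse is provided as a resampling
  operation (`apply_rigid_inverse`), exact up to interpolation.
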