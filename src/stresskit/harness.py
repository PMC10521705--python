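"""Experimental machinery: seeding, severity sweeps, metrics, RM-ANOVA, CSV.

A sweep applies one artifact at a time over a severity grid to a cohort of
studies, runs a segmentation function on each corrupted study, and scores
it against the *unmodified* tumor mask.  Randomness is pseudorandomized by
a seed derived from (subject id, artifact type, sequence) — never from the
severity level — so the shape of an artifact does not vary within a
subject as its severity is swept.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from . import acquisition_artifacts as acq
from . import preprocessing_artifacts as prep
from .phantom import FakeSkullParams, make_fake_skull, remove_fake_skull
from .volume_model import EmptyMaskError, SequenceKind, Study

# ---------------------------------------------------------------------------
# Deterministic seeding


@dataclass(frozen=True)
class ArtifactSeedKey:
    """Key of the pseudorandomization scheme: subject, artifact type, sequence.

    The severity level is deliberately absent so one subject keeps one
    artifact geometry across a sweep.  ``sequence`` is "ALL" for artifacts
    applied to the whole study.
    """

    subject_id: str
    artifact_type: str
    sequence: str = "ALL"

    def __post_init__(self) -> None:
        if not (self.subject_id and self.artifact_type and self.sequence):
            raise ValueError("ArtifactSeedKey fields must be non-empty")


def derive_seed(key: ArtifactSeedKey) -> int:
    """Stable 63-bit seed from the key (BLAKE2b of the UTF-8 join).

    Identical across runs and platforms; keys differing in any field give
    independent seeds (collision probability < 2**-32 for realistic key
    counts).
    """
    payload = "\x1f".join((key.subject_id, key.artifact_type, key.sequence))
    digest = hashlib.blake2b(payload.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") & (2**63 - 1)


# ---------------------------------------------------------------------------
# Metrics


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    denom = mask_a.sum() + mask_b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(mask_a & mask_b) / denom)


def confusion_metrics(pred_mask: np.ndarray, truth_mask: np.ndarray) -> dict:
    """Sensitivity, specificity and the raw confusion counts.

    Undefined ratios (empty truth class) are reported as NaN with a flag.
    """
    pred = np.asarray(pred_mask, dtype=bool)
    truth = np.asarray(truth_mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "undefined": (tp + fn) == 0 or (tn + fp) == 0,
    }


def auroc(score_volume: np.ndarray, truth_mask: np.ndarray) -> float:
    """Rank-based AUROC (Mann-Whitney, midranks for ties); NaN if one class."""
    scores = np.asarray(score_volume, dtype=float).ravel()
    truth = np.asarray(truth_mask, dtype=bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("score volume and truth mask have different sizes")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA summary (levels as treatments)."""

    f_statistic: float
    df_treatment: int
    df_error: int
    p_value: float
    significant: bool  # at p < 0.01, the study's threshold

    def as_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "df_treatment": self.df_treatment,
            "df_error": self.df_error,
            "p_value": self.p_value,
            "significant": self.significant,
        }


def rm_anova(dice_matrix: np.ndarray, alpha: float = 0.01) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x levels matrix.

    Sums of squares are partitioned definitionally into treatment, subject
    and error; F = MS_treatment / MS_error with df (k-1) and (k-1)(n-1),
    and the p-value comes from the F distribution (no sphericity
    correction).
    """
    x = np.asarray(dice_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("dice_matrix must be 2D (subjects x levels)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 levels, got {n} x {k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dice_matrix has missing cells; the design must be complete")
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    # centering each effect on the mean of its own means keeps the degenerate
    # cases exact (identical columns -> SS_treatment is exactly 0)
    ss_treat = n * ((col_means - col_means.mean()) ** 2).sum()
    ss_subj = k * ((row_means - row_means.mean()) ** 2).sum()
    ss_total = ((x - x.mean()) ** 2).sum()
    ss_err = max(ss_total - ss_treat - ss_subj, 0.0)
    df_t = k - 1
    df_e = (k - 1) * (n - 1)
    ms_t = ss_treat / df_t
    ms_e = ss_err / df_e
    if ms_e <= 0:
        f = 0.0 if ms_t == 0 else float("inf")
        p = 1.0 if ms_t == 0 else 0.0
    else:
        f = float(ms_t / ms_e)
        p = float(stats.f.sf(f, df_t, df_e))
    return RMAnovaResult(f, df_t, df_e, p, p < alpha)


# ---------------------------------------------------------------------------
# Calibration


def intensity_change_summary(
    original: Study,
    altered: Study,
    bin_edges: np.ndarray | None = None,
) -> dict[str, dict]:
    """Per-sequence distribution of |altered - original| over brain voxels.

    Returns, per sequence, the mean, median, 95th percentile and histogram
    counts at fixed bin edges (counts sum to the brain voxel count).
    """
    if original.shape != altered.shape:
        raise ValueError("studies are on different grids")
    brain = original.brain_mask
    diffs = {
        kind: np.abs(altered.volume(kind).data[brain] - original.volume(kind).data[brain])
        for kind in original.sequences
    }
    if bin_edges is None:
        top = max(float(d.max()) for d in diffs.values())
        bin_edges = np.linspace(0.0, max(top, 1e-9), 65)
    out = {}
    for kind, d in diffs.items():
        counts, _ = np.histogram(np.clip(d, bin_edges[0], bin_edges[-1]), bins=bin_edges)
        out[kind.value] = {
            "mean": float(d.mean()),
            "median": float(np.median(d)),
            "p95": float(np.percentile(d, 95)),
            "hist_counts": counts,
            "bin_edges": np.asarray(bin_edges),
        }
    return out


# ---------------------------------------------------------------------------
# Baseline segmenter (a deliberately simple, transparent FLAIR thresholder)


def baseline_segmenter(study: Study) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-based FLAIR segmenter standing in for a trained model.

    Score = FLAIR intensity min-max normalized over the brain; mask =
    scores above the Otsu threshold of the brain scores, morphologically
    opened (radius-1 ball) and reduced to the largest connected
    component.  Deterministic; mask is always a subset of the brain mask.
    """
    if not study.brain_mask.any():
        raise EmptyMaskError("baseline segmenter requires a non-empty brain mask")
    flair = study.volume(SequenceKind.FLAIR).data
    vals = flair[study.brain_mask]
    lo, hi = float(vals.min()), float(vals.max())
    score = np.zeros(study.shape)
    if hi > lo:
        score[study.brain_mask] = (vals - lo) / (hi - lo)
    thresh = threshold_otsu(score[study.brain_mask]) if hi > lo else 0.5
    mask = (score > thresh) & study.brain_mask
    mask = ndimage.binary_opening(mask, structure=ball(1))
    mask &= study.brain_mask
    if mask.any():
        labels, n = ndimage.label(mask)
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            mask = labels == int(np.argmax(counts))
    return mask, score


# ---------------------------------------------------------------------------
# Sweep configuration (severity grids of the experiments)

PER_SEQUENCE_ARTIFACTS = ("motion", "aliasing", "misalign")
WHOLE_STUDY_ARTIFACTS = ("signal_loss", "inhomogeneity", "skull_strip")
ALL_ARTIFACTS = PER_SEQUENCE_ARTIFACTS + ("mislabel",) + WHOLE_STUDY_ARTIFACTS


@dataclass
class SweepConfig:
    """One artifact's severity grid and sequence scope.

    ``levels`` is a list of parameter dicts, one per severity level;
    ``sequences`` lists the target sequences for per-sequence artifacts
    (ignored for whole-study artifacts and for mislabeling, whose levels
    already enumerate the 13 slot/content conditions).
    ``include_control`` prepends an explicit no-artifact condition.
    """

    artifact_type: str
    levels: list[dict]
    sequences: tuple[SequenceKind, ...] = tuple(SequenceKind)
    include_control: bool = False
    mode: str = "3D"  # motion reconstruction mode
    components: str = "both"  # motion / misalignment components
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.artifact_type not in ALL_ARTIFACTS and self.artifact_type != "none":
            raise ValueError(f"unknown artifact type {self.artifact_type!r}")
        if not self.levels:
            raise ValueError("SweepConfig needs at least one level")


#: Motion severity factor grid: factor k scales rotation 3.75° -> 45°
#: (up-down), 0.9375° -> 11.25° (left-right) and translation 0.5 -> 6 px.
MOTION_FACTORS = tuple(range(1, 13))
SIGNAL_LOSS_RADII = tuple(range(5, 55, 5))
ALIAS_COUNTS = tuple(range(1, 9))
INHOMOGENEITY_GAINS = tuple(
    (round(1.0 + 0.05 * k, 2), round(1.0 - 0.05 * k, 2)) for k in range(1, 9)
)


def table_sweep_config(
    artifact_type: str,
    mode: str = "3D",
    components: str = "both",
    sequences: Iterable[SequenceKind] = tuple(SequenceKind),
    include_control: bool = False,
) -> SweepConfig:
    """The standard severity grid for one artifact type."""
    if artifact_type == "motion" or artifact_type == "misalign":
        levels = [
            {"factor": k, "max_rot_updown_deg": 3.75 * k, "max_translation_px": 0.5 * k}
            for k in MOTION_FACTORS
        ]
    elif artifact_type == "signal_loss":
        levels = [{"base_radius_px": float(r)} for r in SIGNAL_LOSS_RADII]
    elif artifact_type == "aliasing":
        levels = [{"n_aliases": n} for n in ALIAS_COUNTS]
    elif artifact_type == "inhomogeneity":
        levels = [{"gain_high": gh, "gain_low": gl} for gh, gl in INHOMOGENEITY_GAINS]
    elif artifact_type == "mislabel":
        levels = [
            {"replaced": spec.replaced.value, "substituted": spec.substituted.value}
            for spec in prep.enumerate_mislabel_conditions()
        ]
    elif artifact_type == "skull_strip":
        levels = [{"retained_fraction": p} for p in prep.SKULL_STRIP_FRACTIONS]
    else:
        raise ValueError(f"unknown artifact type {artifact_type!r}")
    return SweepConfig(
        artifact_type=artifact_type,
        levels=levels,
        sequences=tuple(sequences),
        include_control=include_control,
        mode=mode,
        components=components,
    )


# ---------------------------------------------------------------------------
# Sweep execution

#: Stable CSV column order.
RECORD_COLUMNS = (
    "subject_id",
    "grade_label",
    "artifact_type",
    "sequence",
    "level_index",
    "level_params",
    "seed",
    "dice",
    "sensitivity",
    "specificity",
    "auroc",
    "tp",
    "fp",
    "fn",
    "tn",
    "geometry_fingerprint",
    "flag",
)


def _fingerprint(info: dict | None) -> str:
    if not info:
        return ""

    def _round(o):
        if isinstance(o, float):
            return round(o, 6)
        if isinstance(o, dict):
            return {k: _round(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [_round(v) for v in o]
        return o

    return json.dumps(_round(info), sort_keys=True, separators=(",", ":"))


def apply_artifact(
    study_with_skull: Study,
    artifact_type: str,
    params: dict,
    seed: int,
    sequence: SequenceKind | None = None,
    mode: str = "3D",
    components: str = "both",
) -> tuple[Study, dict | None]:
    """Apply one artifact condition; returns (corrupted study, geometry info).

    ``study_with_skull`` should already carry the fake skull where the
    pipeline calls for one.  Skull-strip is not handled here — it needs
    the candidate mask and replaces the removal step.
    """
    if artifact_type == "none":
        return study_with_skull.copy(), None
    if artifact_type == "motion":
        spec = acq.MotionSpec(
            target_sequence=sequence, mode=mode, components=components,
            max_rot_updown_deg=params["max_rot_updown_deg"],
            max_translation_px=params["max_translation_px"],
        )
        return acq.simulate_motion(study_with_skull, spec, seed, return_info=True)
    if artifact_type == "signal_loss":
        spec = acq.SusceptibilitySpec(base_radius_px=params["base_radius_px"])
        return acq.simulate_signal_loss(study_with_skull, spec, seed, return_info=True)
    if artifact_type == "aliasing":
        spec = acq.AliasSpec(n_aliases=params["n_aliases"], target_sequence=sequence)
        return acq.simulate_aliasing(study_with_skull, spec, return_info=True)
    if artifact_type == "inhomogeneity":
        spec = acq.InhomogeneitySpec(gain_high=params["gain_high"], gain_low=params["gain_low"])
        out, _bias, info = acq.simulate_inhomogeneity(
            study_with_skull, spec, seed, return_info=True
        )
        return out, info
    if artifact_type == "mislabel":
        spec = prep.MislabelSpec(
            SequenceKind(params["replaced"]), SequenceKind(params["substituted"])
        )
        return prep.mislabel_sequence(study_with_skull, spec), None
    if artifact_type == "misalign":
        spec = prep.MisalignSpec(
            target_sequence=sequence, components=components,
            max_rot_updown_deg=params["max_rot_updown_deg"],
            max_translation_px=params["max_translation_px"],
        )
        out, info, _t = prep.misalign_sequence(study_with_skull, spec, seed, return_info=True)
        return out, info
    raise ValueError(f"unknown artifact type {artifact_type!r}")


def _conditions(config: SweepConfig) -> list[tuple[str, int, dict]]:
    """Expand a config into (sequence label, level index, params) tuples."""
    conds: list[tuple[str, int, dict]] = []
    if config.include_control:
        conds.append(("ALL", -1, {}))
    if config.artifact_type in PER_SEQUENCE_ARTIFACTS:
        for seq in config.sequences:
            for i, params in enumerate(config.levels):
                conds.append((seq.value, i, params))
    elif config.artifact_type == "mislabel":
        for i, params in enumerate(config.levels):
            label = "control" if params["replaced"] == params["substituted"] else params["replaced"]
            conds.append((label, i, params))
    else:
        for i, params in enumerate(config.levels):
            conds.append(("ALL", i, params))
    return conds


def run_sweep(
    studies: Sequence[Study],
    segmenter: Callable[[Study], tuple[np.ndarray, np.ndarray]],
    config: SweepConfig,
    output_path: str | Path | None = None,
    skull_params: FakeSkullParams | None = None,
    add_fake_skull: bool = True,
) -> tuple[pd.DataFrame, dict[str, RMAnovaResult]]:
    """Run one artifact's severity sweep over a cohort.

    For each (subject, sequence-if-applicable, level): derive the seed,
    add the fake skull, apply the artifact, remove the fake skull (or, for
    skull-strip failure, retain part of it), segment, and score against
    the unmodified tumor mask.  Returns the records (one row per
    condition) and per-(artifact, sequence) repeated-measures ANOVA over
    the severity levels.  A failing condition is flagged and the sweep
    continues.
    """
    if not studies:
        raise ValueError("run_sweep needs at least one study")
    conds = _conditions(config)
    rows: list[dict] = []
    for study in studies:
        if add_fake_skull:
            skulled, skull_mask = make_fake_skull(study, skull_params)
        else:
            skulled, skull_mask = study, np.zeros(study.shape, dtype=bool)
        for seq_label, level_index, params in conds:
            key_seq = seq_label if config.artifact_type in PER_SEQUENCE_ARTIFACTS else "ALL"
            seed = derive_seed(ArtifactSeedKey(study.subject_id, config.artifact_type, key_seq))
            row = {
                "subject_id": study.subject_id,
                "grade_label": study.grade_label,
                "artifact_type": config.artifact_type if level_index >= 0 else "none",
                "sequence": seq_label,
                "level_index": level_index,
                "level_params": json.dumps(params, sort_keys=True),
                "seed": seed,
                "geometry_fingerprint": "",
                "flag": "",
            }
            try:
                if level_index < 0:
                    corrupted, info = skulled.copy(), None
                elif config.artifact_type == "skull_strip":
                    spec = prep.SkullStripSpec(retained_fraction=params["retained_fraction"])
                    corrupted, _retained, info = prep.fail_skull_strip(
                        skulled, skull_mask, spec, seed, return_info=True
                    )
                else:
                    seq = SequenceKind(seq_label) if config.artifact_type in PER_SEQUENCE_ARTIFACTS else None
                    corrupted, info = apply_artifact(
                        skulled, config.artifact_type if level_index >= 0 else "none",
                        params, seed, seq, config.mode, config.components,
                    )
                if add_fake_skull and config.artifact_type != "skull_strip":
                    corrupted = remove_fake_skull(corrupted, skull_mask)
                pred_mask, score = segmenter(corrupted)
                cm = confusion_metrics(pred_mask, study.tumor_mask)
                row.update(
                    dice=dice(pred_mask, study.tumor_mask),
                    sensitivity=cm["sensitivity"],
                    specificity=cm["specificity"],
                    auroc=auroc(score, study.tumor_mask),
                    tp=cm["tp"], fp=cm["fp"], fn=cm["fn"], tn=cm["tn"],
                    geometry_fingerprint=_fingerprint(info),
                )
            except Exception as exc:  # flag and continue: one bad cell must not kill a sweep
                warnings.warn(
                    f"condition failed for {study.subject_id} "
                    f"({config.artifact_type}, {seq_label}, level {level_index}): {exc}",
                    stacklevel=2,
                )
                row.update(
                    dice=np.nan, sensitivity=np.nan, specificity=np.nan, auroc=np.nan,
                    tp=-1, fp=-1, fn=-1, tn=-1, flag=f"error: {type(exc).__name__}",
                )
            rows.append(row)

    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    anova = sweep_anova(records)
    if output_path is not None:
        write_records_csv(records, output_path)
    return records, anova


def sweep_anova(records: pd.DataFrame) -> dict[str, RMAnovaResult]:
    """Per-(artifact, sequence) RM-ANOVA of Dice over the severity levels."""
    out: dict[str, RMAnovaResult] = {}
    ok = records[(records["flag"] == "") & (records["level_index"] >= 0)]
    for (artifact, sequence), grp in ok.groupby(["artifact_type", "sequence"], sort=True):
        pivot = grp.pivot_table(index="subject_id", columns="level_index", values="dice")
        if pivot.shape[0] >= 2 and pivot.shape[1] >= 2 and not pivot.isna().any().any():
            out[f"{artifact}:{sequence}"] = rm_anova(pivot.to_numpy())
    return out


def write_records_csv(records: pd.DataFrame, path: str | Path) -> Path:
    """Write records with a stable column order and float format (UTF-8, RFC 4180)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False, float_format="%.10g", lineterminator="\n", encoding="utf-8")
    return path
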