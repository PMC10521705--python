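"""Acquisition artifact generators: motion, signal loss, aliasing, inhomogeneity."""

import numpy as np
import pytest

from stresskit import (
    AliasSpec,
    InhomogeneitySpec,
    MotionSpec,
    RigidTransform,
    SequenceKind,
    SusceptibilitySpec,
    Volume,
    segment_phase_encodes,
    simulate_aliasing,
    simulate_inhomogeneity,
    simulate_motion,
    simulate_signal_loss,
)

FLAIR = SequenceKind.FLAIR


def _rel_err(a, b):
    return np.abs(a - b).max() / max(np.abs(b).max(), 1e-300)


class TestMotion:
    def test_null_motion_is_identity_within_fft_error(self, skulled_study):
        study, _ = skulled_study
        out = simulate_motion(
            study, MotionSpec(max_rot_updown_deg=0.0, max_translation_px=0.0), seed=3
        )
        assert _rel_err(out.volume(FLAIR).data, study.volume(FLAIR).data) < 1e-6

    def test_non_target_sequences_bit_identical(self, skulled_study):
        study, _ = skulled_study
        for mode in ("3D", "2D"):
            out = simulate_motion(
                study, MotionSpec(mode=mode, max_rot_updown_deg=15.0), seed=3
            )
            for kind in (SequenceKind.T1W, SequenceKind.T1GD, SequenceKind.T2W):
                np.testing.assert_array_equal(
                    out.volume(kind).data, study.volume(kind).data
                )

    def test_2d_and_3d_reconstructions_differ(self, skulled_study):
        study, _ = skulled_study
        a = simulate_motion(study, MotionSpec(mode="3D", max_rot_updown_deg=15.0), seed=3)
        b = simulate_motion(study, MotionSpec(mode="2D", max_rot_updown_deg=15.0), seed=3)
        assert not np.array_equal(a.volume(FLAIR).data, b.volume(FLAIR).data)

    def test_determinism(self, skulled_study):
        study, _ = skulled_study
        a = simulate_motion(study, MotionSpec(max_rot_updown_deg=30.0), seed=9)
        b = simulate_motion(study, MotionSpec(max_rot_updown_deg=30.0), seed=9)
        np.testing.assert_array_equal(a.volume(FLAIR).data, b.volume(FLAIR).data)

    def test_two_segment_splice_matches_direct_dft_oracle(self):
        """n_states=2 with a forced integer shift reproduces the closed-form
        k-space splice, computed with an independent DFT-matrix oracle."""
        rng = np.random.default_rng(5)
        data = rng.uniform(1.0, 2.0, size=(16, 16, 16))
        study = _single_channel_study(data)
        shift = RigidTransform(translation_px=(2, 0, 0), interpolation="nearest")
        out = simulate_motion(
            study, MotionSpec(n_states=2, target_sequence=FLAIR),
            seed=0, forced_transforms=[shift],
        )

        n = 16
        j, k = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        F = np.exp(-2j * np.pi * j * k / n) / np.sqrt(n)

        def dft3(x):
            return np.einsum("ai,bj,ck,ijk->abc", F, F, F, x)

        def idft3(x):
            G = F.conj()
            return np.einsum("ai,bj,ck,ijk->abc", G, G, G, x)

        moved = np.zeros_like(data)
        moved[2:, :, :] = data[:-2, :, :]
        k0, k1 = dft3(data), dft3(moved)
        seg = segment_phase_encodes((16, 16, 16), n_states=2, mode="3D")
        mask = seg.state_mask(1)
        spliced = np.where(mask, k1, k0)
        expected = np.abs(idft3(spliced))
        assert np.abs(out.volume(FLAIR).data - expected).max() < 1e-8

    def test_directions_invariant_across_severity_at_fixed_seed(self, skulled_study):
        study, _ = skulled_study
        infos = []
        for factor in (1, 4, 12):
            _, info = simulate_motion(
                study,
                MotionSpec(max_rot_updown_deg=3.75 * factor,
                           max_translation_px=0.5 * factor),
                seed=21, return_info=True,
            )
            infos.append(info["directions"])
        assert infos[0] == infos[1] == infos[2]

    def test_brain_energy_change_bounded_at_max_severity(self, skulled_study):
        study, _ = skulled_study
        out = simulate_motion(
            study, MotionSpec(max_rot_updown_deg=45.0, max_translation_px=6.0), seed=2
        )
        brain = study.brain_mask
        e0 = (study.volume(FLAIR).data[brain] ** 2).sum()
        e1 = (out.volume(FLAIR).data[brain] ** 2).sum()
        assert abs(e1 - e0) < 0.30 * e0

    def test_negative_maxima_rejected(self):
        with pytest.raises(ValueError):
            MotionSpec(max_rot_updown_deg=-1.0)

    def test_out_of_range_maxima_warn(self):
        with pytest.warns(UserWarning):
            MotionSpec(max_rot_updown_deg=90.0)


def _single_channel_study(data):
    from stresskit import Study

    vols = {k: Volume(data.copy()) for k in SequenceKind}
    brain = data > np.percentile(data, 20)
    tumor = np.zeros(data.shape, dtype=bool)
    return Study("oracle", vols, brain, tumor)


@pytest.fixture(scope="module")
def lossy(skulled_study):
    study, _ = skulled_study
    out, info = simulate_signal_loss(
        study, SusceptibilitySpec(base_radius_px=10.0), seed=11, return_info=True
    )
    return study, out, info


class TestSignalLoss:
    def test_monotone_attenuation(self, lossy):
        study, out, _ = lossy
        for kind in SequenceKind:
            assert np.all(out.volume(kind).data <= study.volume(kind).data + 1e-12)

    def test_t1_extent_smaller_than_flair(self, lossy):
        _, _, info = lossy
        assert info["affected_counts"]["T1W"] < info["affected_counts"]["FLAIR"]
        assert info["affected_counts"]["T1W"] == info["affected_counts"]["T1Gd"]
        assert info["affected_counts"]["T2W"] == info["affected_counts"]["FLAIR"]

    def test_artifact_avoids_tumor(self, lossy):
        study, out, _ = lossy
        for kind in SequenceKind:
            changed = out.volume(kind).data != study.volume(kind).data
            assert not np.any(changed & study.tumor_mask)

    def test_unmodified_voxels_bit_identical(self, lossy):
        study, out, _ = lossy
        flair0 = study.volume(FLAIR).data
        flair1 = out.volume(FLAIR).data
        same = flair1 == flair0
        assert same.sum() > 0.5 * flair0.size  # the artifact is local

    def test_geometry_invariant_across_radius_sweep(self, skulled_study):
        study, _ = skulled_study
        dirs = []
        # radii for which a near-tumor placement fits this phantom's grid
        for r in (5.0, 8.0, 10.0, 12.0):
            _, info = simulate_signal_loss(
                study, SusceptibilitySpec(base_radius_px=r), seed=11, return_info=True
            )
            dirs.append((tuple(info["direction"]), info["margin"]))
        assert len(set(dirs)) == 1

    def test_determinism(self, skulled_study):
        study, _ = skulled_study
        a = simulate_signal_loss(study, SusceptibilitySpec(base_radius_px=10.0), seed=4)
        b = simulate_signal_loss(study, SusceptibilitySpec(base_radius_px=10.0), seed=4)
        np.testing.assert_array_equal(a.volume(FLAIR).data, b.volume(FLAIR).data)


class TestAliasing:
    @pytest.mark.parametrize("n_aliases", [1, 8])
    def test_superposed_copies_closed_form(self, n_aliases):
        """n aliases = n+1 shifted copies of the image along the phase axis."""
        rng = np.random.default_rng(8)
        R = n_aliases + 1
        size = 18 if R == 9 else 16  # pick L divisible by R for exact copies
        data = rng.uniform(1.0, 2.0, size=(size, 8, 8))
        study = _single_channel_study(data)
        out = simulate_aliasing(study, AliasSpec(n_aliases=n_aliases, target_sequence=FLAIR))
        expected = np.abs(sum(np.roll(data, k * size // R, axis=0) for k in range(R)))
        assert np.abs(out.volume(FLAIR).data - expected).max() < 1e-8

    def test_non_target_sequences_bit_identical(self, skulled_study):
        study, _ = skulled_study
        out = simulate_aliasing(study, AliasSpec(n_aliases=3, target_sequence=FLAIR))
        for kind in (SequenceKind.T1W, SequenceKind.T1GD, SequenceKind.T2W):
            np.testing.assert_array_equal(out.volume(kind).data, study.volume(kind).data)

    def test_invalid_alias_count_rejected(self):
        with pytest.raises(ValueError):
            AliasSpec(n_aliases=0)


class TestInhomogeneity:
    def test_unit_gains_are_identity(self, gbm_study):
        out, bias = simulate_inhomogeneity(
            gbm_study, InhomogeneitySpec(gain_high=1.0, gain_low=1.0), seed=5
        )
        np.testing.assert_array_equal(bias, np.ones(gbm_study.shape))
        for kind in SequenceKind:
            np.testing.assert_array_equal(
                out.volume(kind).data, gbm_study.volume(kind).data
            )

    def test_default_gains_attained_exactly_over_brain(self, gbm_study):
        _, bias = simulate_inhomogeneity(gbm_study, InhomogeneitySpec(), seed=5)
        b = bias[gbm_study.brain_mask]
        assert b.max() == pytest.approx(1.25, abs=1e-6)
        assert b.min() == pytest.approx(0.75, abs=1e-6)
        assert np.all((bias >= 0.75 - 1e-12) & (bias <= 1.25 + 1e-12))

    def test_field_geometry_fixed_across_gain_sweep(self, gbm_study):
        fields, seed_sets = [], []
        for gh, gl in ((1.05, 0.95), (1.25, 0.75), (1.40, 0.60)):
            _, bias, info = simulate_inhomogeneity(
                gbm_study, InhomogeneitySpec(gain_high=gh, gain_low=gl),
                seed=5, return_info=True,
            )
            fields.append((bias - gl) / (gh - gl))
            seed_sets.append(tuple(map(tuple, info["seeds"])))
        # same seed locations -> one fixed field geometry, rescaled by the gains
        assert seed_sets[0] == seed_sets[1] == seed_sets[2]
        np.testing.assert_allclose(fields[0], fields[1], atol=1e-12)
        np.testing.assert_allclose(fields[1], fields[2], atol=1e-12)
        # determinism at equal gains is bit-exact
        _, bias_a = simulate_inhomogeneity(gbm_study, InhomogeneitySpec(), seed=5)
        _, bias_b = simulate_inhomogeneity(gbm_study, InhomogeneitySpec(), seed=5)
        np.testing.assert_array_equal(bias_a, bias_b)

    def test_all_sequences_share_one_field(self, gbm_study):
        out, bias = simulate_inhomogeneity(gbm_study, InhomogeneitySpec(), seed=6)
        brain = gbm_study.brain_mask
        for kind in SequenceKind:
            np.testing.assert_allclose(
                out.volume(kind).data[brain],
                gbm_study.volume(kind).data[brain] * bias[brain],
                rtol=1e-12,
            )

    def test_inverted_gains_rejected(self):
        with pytest.raises(ValueError):
            InhomogeneitySpec(gain_high=0.9, gain_low=1.1)
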