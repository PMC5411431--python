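"""Epoching, baseline correction, downsampling and vector assembly."""
from __future__ import annotations

import numpy as np
import pytest

import errpdecode as ed
from errpdecode.features import (
    EPOCH_SAMPLES,
    N_BINS,
    PRE_SAMPLES,
    POST_SAMPLES,
    TrialEpoch,
    feature_names,
)
from errpdecode.montage import SCALP_CHANNELS

from conftest import dummy_meta


class TestExtractEpoch:
    def test_length_is_240(self, small_rec):
        onset = int(small_rec.onset_samples()[0])
        epoch = ed.extract_epoch(small_rec, onset)
        assert epoch.samples.shape == (56, EPOCH_SAMPLES)

    def test_onset_at_sample_40_starts_at_zero(self, small_rec):
        epoch = ed.extract_epoch(small_rec, PRE_SAMPLES)
        assert np.allclose(epoch.samples[:, 0],
                           small_rec.samples[:56, 0])

    def test_cold_start_mirror_pads(self, small_rec):
        epoch = ed.extract_epoch(small_rec, 10)
        assert epoch.samples.shape == (56, EPOCH_SAMPLES)
        expect = np.pad(small_rec.samples[:56, :10 + POST_SAMPLES],
                        ((0, 0), (30, 0)), mode="reflect")
        assert np.array_equal(epoch.samples, expect)

    def test_onset_past_end_rejected(self, small_rec):
        with pytest.raises(IndexError):
            ed.extract_epoch(small_rec, small_rec.n_samples - 1)


class TestBaselineCorrect:
    def test_pre_onset_mean_is_zero(self, small_rec):
        for onset in small_rec.onset_samples()[:5]:
            epoch = ed.baseline_correct(ed.extract_epoch(small_rec, int(onset)))
            base = epoch.samples[:, :PRE_SAMPLES].mean(axis=1)
            assert np.allclose(base, 0.0, atol=1e-12)

    def test_constant_channel_becomes_zero(self):
        epoch = TrialEpoch(np.full((2, EPOCH_SAMPLES), 7.5), ("Cz", "Fz"))
        out = ed.baseline_correct(epoch)
        assert np.allclose(out.samples, 0.0)

    def test_step_offsets_subtract(self):
        samples = np.concatenate([np.full(PRE_SAMPLES, 2.0),
                                  np.full(POST_SAMPLES, 5.0)])[None, :]
        out = ed.baseline_correct(TrialEpoch(samples, ("Cz",)))
        assert np.allclose(out.samples[0, PRE_SAMPLES:], 3.0)


class TestDownsample:
    def test_eight_bins(self, small_rec):
        epoch = ed.baseline_correct(
            ed.extract_epoch(small_rec, int(small_rec.onset_samples()[0])))
        assert ed.downsample_epoch(epoch).shape == (56, N_BINS)

    def test_constant_channel(self):
        epoch = TrialEpoch(np.ones((1, EPOCH_SAMPLES)), ("Cz",))
        assert np.allclose(ed.downsample_epoch(epoch), 1.0)

    def test_ramp_bin_means(self):
        post = np.arange(POST_SAMPLES, dtype=float)
        samples = np.concatenate([np.zeros(PRE_SAMPLES), post])[None, :]
        out = ed.downsample_epoch(TrialEpoch(samples, ("Cz",)))
        assert np.allclose(out[0], [12.0, 37.0, 62.0, 87.0,
                                    112.0, 137.0, 162.0, 187.0])


class TestMetaFeatures:
    def test_nine_values_with_expected_entries(self):
        meta = dummy_meta(0, True)
        epoch = TrialEpoch(np.full((2, EPOCH_SAMPLES), 2.0), ("Cz", "Fz"),
                           meta)
        vec = ed.compute_meta(meta, epoch)
        assert vec.shape == (9,)
        assert vec[0] == pytest.approx(2.0)     # grand mean
        assert vec[1] == pytest.approx(0.0)     # population variance
        assert vec[2] == meta.session

    def test_sequence_and_totals_encoding(self, profile):
        plan5 = ed.make_session_plan(profile, 5, seed=3)
        last = plan5[-1]
        assert last.feedback_index == 100 and last.total_feedback == 340
        epoch = TrialEpoch(np.zeros((1, EPOCH_SAMPLES)), ("Cz",), last)
        vec = ed.compute_meta(last, epoch)
        assert vec[6] == 340.0
        assert vec[8] in (0.0, 1.0)


class TestAssemble:
    @pytest.mark.parametrize("n_channels, expected",
                             [(56, 457), (35, 289), (1, 17)])
    def test_vector_length_formula(self, n_channels, expected):
        chans = SCALP_CHANNELS[:n_channels]
        sig = {ch: np.zeros(N_BINS) for ch in chans}
        vec = ed.assemble(sig, np.zeros(9), chans)
        assert vec.shape == (expected,)
        assert len(feature_names(chans)) == expected

    def test_missing_channel_rejected(self):
        sig = {"Cz": np.zeros(N_BINS)}
        with pytest.raises(KeyError):
            ed.assemble(sig, np.zeros(9), ("Cz", "Fz"))

    def test_channel_major_layout(self):
        sig = {"Cz": np.arange(8.0), "Fz": np.arange(8.0) + 10}
        vec = ed.assemble(sig, np.full(9, -1.0), ("Cz", "Fz"))
        assert np.allclose(vec[:8], np.arange(8.0))
        assert np.allclose(vec[8:16], np.arange(8.0) + 10)
        assert np.allclose(vec[16:], -1.0)


class TestFeatureTable:
    def test_matrix_shape_and_subsets(self, small_table):
        assert small_table.matrix().shape == (20, 457)
        sub = ("Cz", "FCz", "Fz")
        assert small_table.matrix(sub).shape == (20, 8 * 3 + 9)

    def test_subset_meta_moments_are_exact(self, small_table, filtered_rec,
                                           small_plan):
        """Grand mean/variance for a channel subset equal a direct
        recomputation on the subsetted epochs."""
        sub = ("Cz", "FCz", "Pz")
        direct = ed.featurize_trials(filtered_rec, small_plan, channels=sub)
        assert np.allclose(small_table.matrix(sub), direct.matrix(),
                           atol=1e-9)

    def test_trial_order_independence(self, filtered_rec, small_plan):
        """Each trial's signal block depends only on its own window (the
        smoothing context is upstream data, not a trial-order effect)."""
        from errpdecode.features import block_feature_vector

        table = ed.featurize_trials(filtered_rec, small_plan)
        # recompute trial 5 in isolation from its raw window plus the
        # trailing 100 ms of the previous trial's block
        onsets = filtered_rec.onset_samples()
        o, prev = int(onsets[5]), int(onsets[4])
        block = filtered_rec.samples[:56, o - PRE_SAMPLES:o + POST_SAMPLES]
        carry = filtered_rec.samples[:56,
                                     prev + POST_SAMPLES - 20:prev + POST_SAMPLES]
        sig, _ = block_feature_vector(block, carry, small_plan[5],
                                      tuple(filtered_rec.channel_names[:56]))
        assert np.allclose(sig, table.signal[5], atol=1e-12)
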