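"""Segmentation, filtering, interpolation, rejection, re-referencing and
ICA cleanup."""

import logging

import numpy as np
import pytest

from thetareg.containers import ContinuousRecording, DataError
from thetareg.preprocess import (
    filter_epochs,
    interpolate_channels,
    preprocess,
    reject_artifact_trials,
    remove_ocular_components,
    rereference_common_average,
    segment_epochs,
)

from conftest import build_epochs

MARKERS = {"S 10": "neutral", "S 20": "maintain", "S 30": "reappraise"}


def make_continuous(rng, sfreq=100.0, n_sec=40, n_ch=8, markers=()):
    data = rng.standard_normal((n_ch, int(n_sec * sfreq)))
    return ContinuousRecording(
        data=data, sfreq=sfreq,
        channel_labels=[f"ch{i}" for i in range(n_ch)],
        events=list(markers),
    )


def circ_positions(n_ch):
    ang = 2 * np.pi * np.arange(n_ch) / n_ch
    return np.column_stack([np.cos(ang), np.sin(ang), np.full(n_ch, 0.5)])


class TestSegmentation:
    def test_marker_exactly_at_boundary(self, rng):
        sfreq = 100.0
        rec = make_continuous(rng, sfreq=sfreq,
                              markers=[(int(6 * sfreq), "S 20")])
        ep = segment_epochs(rec, MARKERS, circ_positions(8))
        assert ep.n_trials == 1
        # epoch starts at recording sample 0
        assert np.array_equal(ep.data[:, 0, 0], rec.data[:, 0])
        assert ep.time_axis[0] == pytest.approx(-6.0)

    def test_trial_too_close_to_edge_dropped_with_warning(self, rng, caplog):
        sfreq = 100.0
        rec = make_continuous(rng, sfreq=sfreq, markers=[
            (int(5 * sfreq), "S 20"),       # only 5 s of pre-marker data
            (int(10 * sfreq), "S 30"),
        ])
        with caplog.at_level(logging.WARNING, logger="thetareg"):
            ep = segment_epochs(rec, MARKERS, circ_positions(8))
        assert ep.n_trials == 1
        assert ep.condition[0] == "reappraise"
        assert any("outside recording" in r.message for r in caplog.records)

    def test_all_markers_yield_trials(self, rng):
        sfreq = 100.0
        marks = [(int((8 + 13.5 * k) * sfreq), "S 20") for k in range(3)]
        rec = make_continuous(rng, sfreq=sfreq, n_sec=60, markers=marks)
        ep = segment_epochs(rec, MARKERS, circ_positions(8))
        assert ep.n_trials == 3
        assert ep.data.shape[1] == int(13 * sfreq) + 1

    def test_no_markers_raises(self, rng):
        rec = make_continuous(rng)
        with pytest.raises(DataError):
            segment_epochs(rec, MARKERS, circ_positions(8))


class TestFiltering:
    def test_line_noise_removed(self):
        sfreq, n_t = 250.0, 1301
        t = np.arange(n_t) / sfreq
        tone = 10 * np.sin(2 * np.pi * 50 * t)
        ep = build_epochs(np.tile(tone, (3, 2, 1)).transpose(0, 2, 1),
                          sfreq=sfreq)
        out = filter_epochs(ep)
        mid = slice(200, -200)  # away from filter edges
        assert np.sqrt((out.data[:, mid] ** 2).mean()) < \
            0.01 * np.sqrt((ep.data[:, mid] ** 2).mean())

    def test_dc_offset_removed(self, rng):
        ep = build_epochs(rng.standard_normal((2, 1301, 2)) + 100.0, sfreq=250.0)
        out = filter_epochs(ep)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-8

    def test_passband_5hz_attenuation_below_2pct(self):
        sfreq, n_t = 250.0, 3251
        t = np.arange(n_t) / sfreq
        tone = np.sin(2 * np.pi * 5 * t)
        ep = build_epochs(tone[None, :, None] * np.ones((2, 1, 2)), sfreq=sfreq)
        out = filter_epochs(ep)
        mid = slice(500, -500)
        ratio = np.sqrt((out.data[0, mid, 0] ** 2).mean() /
                        (ep.data[0, mid, 0] ** 2).mean())
        assert ratio > 0.98

    def test_low_pass_clipped_below_nyquist_with_warning(self, rng):
        ep = build_epochs(rng.standard_normal((2, 1301, 2)), sfreq=100.0)
        with pytest.warns(UserWarning, match="Nyquist"):
            filter_epochs(ep)

    def test_nonfinite_rejected(self, rng):
        data = rng.standard_normal((2, 1301, 2))
        data[0, 5, 0] = np.nan
        with pytest.raises(DataError):
            filter_epochs(build_epochs(data))

    def test_commutes_with_rereferencing(self, rng):
        ep = build_epochs(rng.standard_normal((6, 1301, 3)), sfreq=250.0)
        a = rereference_common_average(filter_epochs(ep))
        b = filter_epochs(rereference_common_average(ep))
        scale = np.abs(a.data).max()
        assert np.abs(a.data - b.data).max() < 1e-8 * scale


class TestInterpolation:
    def test_leave_one_out_recovers_smooth_topography(self, leadfield, rng):
        """A deep-source (spatially smooth) topography at a held-out channel
        is reconstructed with correlation > 0.95."""
        hm = leadfield.head_model
        n_t, n_tr = 50, 4
        deep = [v for v in range(hm.n_voxels)]
        topo = leadfield.gain[deep[3], 0] + leadfield.gain[deep[10], 1]
        ts = rng.standard_normal((1, n_t, n_tr))
        data = topo[:, None, None] * ts
        ep = build_epochs(data, sfreq=50.0)
        ep.channel_positions = hm.channel_positions
        ep.channel_labels = list(hm.channel_labels)
        bad = hm.channel_labels[10]
        out = interpolate_channels(ep, [bad])
        a, b = out.data[10].ravel(), ep.data[10].ravel()
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.95

    def test_empty_bad_list_is_identity(self, rng):
        ep = build_epochs(rng.standard_normal((5, 20, 2)))
        out = interpolate_channels(ep, [])
        assert np.array_equal(out.data, ep.data)

    def test_duplicates_deduplicated(self, leadfield, rng):
        hm = leadfield.head_model
        data = rng.standard_normal((hm.n_channels, 30, 2))
        ep = build_epochs(data)
        ep.channel_positions = hm.channel_positions
        ep.channel_labels = list(hm.channel_labels)
        bad = hm.channel_labels[0]
        once = interpolate_channels(ep, [bad])
        twice = interpolate_channels(ep, [bad, bad])
        assert np.array_equal(once.data, twice.data)

    def test_all_bad_raises(self, rng):
        ep = build_epochs(rng.standard_normal((5, 20, 2)))
        with pytest.raises(DataError):
            interpolate_channels(ep, ep.channel_labels)


class TestRejection:
    def test_planted_spike_removed(self, rng):
        data = rng.standard_normal((4, 100, 12))
        data[:, 40, 7] += 10 * np.abs(data).max()
        ep = build_epochs(data)
        out, log = reject_artifact_trials(ep)
        assert log.rejected_trials == [7]
        assert out.n_trials == 11

    def test_surviving_trials_unaltered(self, rng):
        data = rng.standard_normal((4, 100, 12))
        data[:, 40, 7] += 10 * np.abs(data).max()
        ep = build_epochs(data)
        out, _ = reject_artifact_trials(ep)
        keep = [k for k in range(12) if k != 7]
        assert np.array_equal(out.data, ep.data[:, :, keep])

    def test_homogeneous_trials_kept(self, rng):
        ep = build_epochs(rng.standard_normal((4, 100, 10)))
        out, log = reject_artifact_trials(ep)
        assert out.n_trials == 10
        assert log.rejected_trials == []

    def test_infinite_threshold_is_identity(self, rng):
        data = rng.standard_normal((4, 100, 10))
        data[:, :, 2] *= 50
        ep = build_epochs(data)
        out, _ = reject_artifact_trials(ep, z_threshold=np.inf)
        assert out.n_trials == 10

    def test_all_rejected_raises(self, rng):
        ep = build_epochs(rng.standard_normal((4, 100, 3)))
        with pytest.raises(DataError, match="z_threshold"):
            reject_artifact_trials(ep, z_threshold=-1.0)


class TestRereference:
    def test_channel_mean_is_zero(self, rng):
        ep = build_epochs(rng.standard_normal((6, 100, 4)))
        out = rereference_common_average(ep)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_idempotent(self, rng):
        ep = build_epochs(rng.standard_normal((6, 100, 4)))
        once = rereference_common_average(ep)
        twice = rereference_common_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_bipolar_differences_preserved(self, rng):
        ep = build_epochs(rng.standard_normal((6, 100, 4)))
        out = rereference_common_average(ep)
        assert np.allclose(out.data[2] - out.data[4],
                           ep.data[2] - ep.data[4], atol=1e-12)


class TestICA:
    @staticmethod
    def _epochs_with_drift(rng, drift_scale):
        n_ch, n_t, n_tr = 10, 400, 6
        mix = rng.standard_normal((n_ch, 6))
        sources = rng.standard_normal((6, n_t * n_tr))
        X = mix @ sources
        # slow frontal drift concentrated on the proxy channels
        drift = np.cumsum(rng.standard_normal(n_t * n_tr))
        drift = drift / np.abs(drift).max()
        topo = np.zeros(n_ch)
        topo[:3] = [1.0, 0.9, 0.3]
        X = X + drift_scale * topo[:, None] * drift[None, :]
        data = X.reshape(n_ch, n_tr, n_t).transpose(0, 2, 1)
        ep = build_epochs(data, sfreq=100.0, t0=0.0)
        ep.channel_labels = ["Fp1", "Fp2"] + [f"ch{i}" for i in range(n_ch - 2)]
        return ep, drift

    def test_planted_drift_suppressed(self, rng):
        ep, drift = self._epochs_with_drift(rng, drift_scale=40.0)
        out, n_removed = remove_ocular_components(ep, n_components=8, seed=0)
        assert n_removed >= 1

        def corr_with_drift(rec):
            X = rec.data.transpose(0, 2, 1).reshape(rec.n_channels, -1)
            return max(abs(np.corrcoef(x, drift)[0, 1]) for x in X)

        assert corr_with_drift(out) < 0.2 * corr_with_drift(ep)

    def test_no_removal_is_identity(self, rng):
        ep, _ = self._epochs_with_drift(rng, drift_scale=0.0)
        out, n_removed = remove_ocular_components(
            ep, r_threshold=1.1, n_components=8)  # nothing can exceed 1.1
        assert n_removed == 0
        assert np.array_equal(out.data, ep.data)

    def test_specificity_on_clean_data(self, rng):
        ep, _ = self._epochs_with_drift(rng, drift_scale=0.0)
        _, n_removed = remove_ocular_components(ep, n_components=8, seed=0)
        assert n_removed <= 1

    def test_missing_proxy_raises(self, rng):
        ep = build_epochs(rng.standard_normal((4, 100, 3)))
        with pytest.raises(DataError):
            remove_ocular_components(ep)


class TestFullChain:
    def test_provenance_order(self, leadfield, rng):
        hm = leadfield.head_model
        data = rng.standard_normal((hm.n_channels, 1301, 6))
        ep = build_epochs(data, sfreq=100.0)
        ep.channel_positions = hm.channel_positions
        ep.channel_labels = list(hm.channel_labels)
        with pytest.warns(UserWarning, match="Nyquist"):
            out, log, n_ica = preprocess(ep, run_ica=True, seed=0)
        p = out.provenance
        assert p.filtered and p.interpolated and p.rejected
        assert p.rereferenced and p.ica_cleaned
        assert sum(log.surviving_per_condition.values()) == out.n_trials
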