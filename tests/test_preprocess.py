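"""Epoching, artifact rejection, spline interpolation, filtering,
referencing, spatial smoothing and averaging."""

import numpy as np
import pytest
import scipy.signal

from crterp.io import Recording
from crterp.preprocess import (
    Epochs,
    PreprocessError,
    average_erp,
    average_reference,
    bandpass,
    epoch,
    interpolate_bad_channels,
    n_epoch_samples,
    preprocess_recording,
    reject_artifacts,
    spatial_smooth,
)


def _rec_with_events(n_ch=4, n_samp=4000, srate=512.0, events=None, seed=0):
    rng = np.random.default_rng(seed)
    return Recording(rng.normal(size=(n_ch, n_samp)), srate,
                     [f"c{i}" for i in range(n_ch)],
                     events or [(500, "New", True), (1500, "Rep3", True)])


class TestEpoch:
    def test_default_window_gives_307_samples(self):
        assert n_epoch_samples((-50, 550), 512.0) == 307
        eps = epoch(_rec_with_events())
        assert eps.data.shape == (2, 4, 307)

    def test_event_at_recording_start_is_edge_flagged(self):
        eps = epoch(_rec_with_events(events=[(0, "New", True), (1000, "New", True)]))
        assert eps.n_trials == 1
        assert any(e["reason"] == "edge" for e in eps.log)

    def test_incorrect_responses_dropped_with_log(self):
        eps = epoch(_rec_with_events(events=[(500, "New", False), (1500, "Rep3", True)]))
        assert eps.conditions == ["Rep3"]
        assert any(e["reason"] == "incorrect_response" for e in eps.log)

    def test_all_incorrect_gives_explicit_empty_result(self):
        eps = epoch(_rec_with_events(events=[(500, "New", False)]))
        assert eps.n_trials == 0 and eps.data.shape[0] == 0

    def test_time_axis_starts_at_window_onset(self):
        eps = epoch(_rec_with_events())
        t = eps.times_ms()
        assert t[0] == -50.0 and t[-1] < 550.0


class TestReject:
    def _epochs(self, data):
        return Epochs(data, ["New"] * data.shape[0], 512.0, (-50, 550))

    def test_boundary_amplitudes_retained(self):
        data = np.zeros((2, 3, 307))
        data[0, 1, 5] = 99.9
        data[1, 2, 6] = 100.0  # rejection requires strictly > threshold
        kept, rejections = reject_artifacts(self._epochs(data), 100.0)
        assert kept.n_trials == 2 and rejections == []

    def test_suprathreshold_epoch_rejected_with_first_violation_logged(self):
        data = np.zeros((3, 3, 307))
        data[1, 2, 17] = -120.0
        kept, rejections = reject_artifacts(self._epochs(data), 100.0)
        assert kept.n_trials == 2
        assert rejections[0]["trial"] == 1
        assert (rejections[0]["channel"], rejections[0]["sample"]) == (2, 17)

    def test_infinite_threshold_retains_all(self):
        data = np.full((4, 2, 307), 1e6)
        kept, _ = reject_artifacts(self._epochs(data), np.inf)
        assert kept.n_trials == 4

    def test_planted_blinks_rejected_exactly(self, layout):
        from crterp.sequence import generate_crt
        from crterp.simulate import default_ground_truth, simulate_raw_with_artifacts

        seq = generate_crt(n_pictures=8, n_catch=2, seed=0)
        truth = default_ground_truth(layout, seed=0, noise_sd=0.5)
        planted = [2, 5, 7]
        rec, info = simulate_raw_with_artifacts(
            seq, truth, layout=layout, stim_ms=600.0, isi_ms=200.0,
            blink_trials=planted, blink_amp=150.0, seed=1,
        )
        assert info["contaminated_trials"] == planted
        eps = epoch(rec)
        kept, rejections = reject_artifacts(eps, 100.0)
        assert sorted(r["trial"] for r in rejections) == planted


class TestInterpolation:
    def test_degree1_field_reconstructed_under_one_percent(self, layout):
        # a pure dipolar (spherical-harmonic degree 1) field is in the
        # spline's span, so removing one channel must be recoverable
        direction = np.array([0.3, 0.8, 0.52])
        field = layout.positions @ direction
        data = np.tile(field[:, None], (1, 5))[None]
        out = interpolate_bad_channels(data, ["Fz"], layout)
        i = layout.index("Fz")[0]
        err = np.abs(out[0, i] - data[0, i]).max()
        assert err < 0.01 * (field.max() - field.min())

    def test_no_bad_channels_is_identity(self, layout):
        data = np.random.default_rng(0).normal(size=(1, 128, 3))
        assert interpolate_bad_channels(data, [], layout) is data

    def test_planted_template_recovered(self, layout):
        from crterp.simulate import make_templates

        tmpl = make_templates(1, layout, seed=3).maps[0]
        data = np.tile(tmpl[:, None], (1, 4))[None] * 7.5
        out = interpolate_bad_channels(data, ["C3", "D2"], layout)
        rec = out[0, :, 0]
        r = np.corrcoef(rec, tmpl)[0, 1]
        assert r > 0.99

    def test_too_many_bad_channels_raises(self, layout):
        with pytest.raises(PreprocessError):
            interpolate_bad_channels(np.zeros((1, 128, 2)), layout.labels[:40], layout)


class TestBandpass:
    @pytest.mark.parametrize("freq,check", [(50.0, "attenuated"), (10.0, "passed")])
    def test_sinusoid_against_closed_form_butterworth(self, freq, check):
        srate = 512.0
        t = np.arange(4096) / srate
        x = np.sin(2 * np.pi * freq * t)[None, None, :]
        y = bandpass(x, (1.0, 30.0), order=2, srate=srate)
        mid = slice(1000, 3000)
        gain = np.abs(y[0, 0, mid]).max() / np.abs(x[0, 0, mid]).max()
        # forward-backward application squares the cascade's magnitude
        _, h_hp = scipy.signal.freqz(*scipy.signal.butter(2, 1.0, "highpass", fs=srate),
                                     worN=[freq], fs=srate)
        _, h_lp = scipy.signal.freqz(*scipy.signal.butter(2, 30.0, "lowpass", fs=srate),
                                     worN=[freq], fs=srate)
        expected = (np.abs(h_hp[0]) * np.abs(h_lp[0])) ** 2
        assert gain == pytest.approx(expected, rel=0.05)
        if check == "attenuated":
            assert gain < 0.12  # closed form: 10.7% after two passes
        else:
            assert gain > 0.95

    def test_constant_signal_removed(self):
        x = np.full((2, 3, 2048), 42.0)
        y = bandpass(x, srate=512.0)
        assert np.abs(y).max() < 1e-6

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(PreprocessError):
            bandpass(np.zeros((1, 2, 100)), (1.0, 300.0), srate=512.0)


class TestReferenceAndSmooth:
    def test_average_reference_zeroes_channel_sums(self):
        x = np.random.default_rng(0).normal(size=(5, 8, 30)) + 3.0
        y = average_reference(x)
        assert np.abs(y.sum(axis=1)).max() < 1e-9 * np.abs(x).max()
        assert np.allclose(average_reference(y), y)  # idempotent

    def test_single_nonzero_channel_scaling(self):
        n = 8
        x = np.zeros((1, n, 1))
        x[0, 3, 0] = 1.0
        y = average_reference(x)
        assert y[0, 3, 0] == pytest.approx((n - 1) / n)

    def test_constant_map_unchanged_by_smoothing(self, layout):
        x = np.full((1, 128, 4), 5.0)
        y = spatial_smooth(x, layout)
        assert np.allclose(y, x)

    def test_spike_is_attenuated_and_spread(self, layout):
        x = np.zeros((1, 128, 1))
        x[0, 60, 0] = 10.0
        y = spatial_smooth(x, layout)
        assert y[0, 60, 0] < 10.0
        neighbors = np.argsort(np.linalg.norm(
            layout.positions - layout.positions[60], axis=1))[1:4]
        assert (y[0, neighbors, 0] > 0).all()

    def test_sigma_zero_is_identity(self, layout):
        x = np.random.default_rng(1).normal(size=(1, 128, 2))
        y = spatial_smooth(x, layout, sigma=1e-9)
        assert np.allclose(y, x, atol=1e-12)


class TestAveraging:
    def _eps(self, data, conds):
        return Epochs(data, conds, 512.0, (-50.0, 550.0))

    def test_identical_epochs_average_to_themselves(self):
        ep = np.random.default_rng(0).normal(size=(3, 2, 307))
        ep[1] = ep[0]
        ep[2] = ep[0]
        erps = average_erp([self._eps(ep, ["New"] * 3)], ["New"], ["a", "b"])
        assert np.allclose(erps.data[0, 0], ep[0])
        assert erps.n_epochs_accepted[0, 0] == 3

    def test_two_epoch_mean_exact(self):
        ep = np.random.default_rng(1).normal(size=(2, 2, 307))
        erps = average_erp([self._eps(ep, ["New", "New"])], ["New"], ["a", "b"])
        assert np.array_equal(erps.data[0, 0], (ep[0] + ep[1]) / 2)

    def test_noise_average_shrinks_like_sqrt_n(self):
        from crterp.microstate import gfp

        rng = np.random.default_rng(2)
        gfps = {}
        for n in (10, 100):
            reps = []
            for _ in range(15):
                ep = rng.normal(size=(n, 16, 307))
                erps = average_erp([self._eps(ep, ["New"] * n)], ["New"],
                                   [f"c{i}" for i in range(16)])
                reps.append(gfp(erps.data[0, 0]).mean())
            gfps[n] = np.mean(reps)
        assert gfps[10] / gfps[100] == pytest.approx(np.sqrt(10), rel=0.1)

    def test_empty_cell_flagged_not_silent(self):
        ep = np.random.default_rng(3).normal(size=(2, 2, 307))
        erps = average_erp([self._eps(ep, ["New", "New"])], ["New", "Rep3"], ["a", "b"])
        assert np.isnan(erps.data[0, 1]).all()
        assert any(e["reason"] == "empty_cell" for e in erps.rejection_log)


def test_full_chain_preserves_planted_topography(layout):
    """Zero-noise synthetic recording -> preprocess chain -> the planted
    window topography survives with spatial correlation > 0.99."""
    from crterp.sequence import generate_crt
    from crterp.simulate import GroundTruth, default_ground_truth, \
        simulate_raw_with_artifacts
    from crterp.microstate import spatial_correlation

    seq = generate_crt(n_pictures=6, n_catch=0, seed=2)
    base = default_ground_truth(layout, seed=4, noise_sd=0.0)
    # single scheduled map per condition: the window interior is then the
    # planted topography alone (adjacent windows would bleed filter
    # ringing of *other* maps into the comparison)
    truth = GroundTruth(base.templates,
                        {c: [((100.0, 400.0), 0, 5.0)] for c in base.conditions},
                        noise_sd=0.0)
    rec, _ = simulate_raw_with_artifacts(seq, truth, layout=layout,
                                         stim_ms=600.0, isi_ms=200.0, seed=0)
    eps = preprocess_recording(rec, layout)
    erps = average_erp([eps], ["New"], layout.labels)
    t = erps.times_ms()
    window = (t >= 150) & (t < 350)
    mean_map = erps.data[0, 0][:, window].mean(axis=1)
    r = spatial_correlation(mean_map, truth.templates.maps[0])
    assert abs(r) > 0.99
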