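"""Signal-processing contracts: MBLL, CAR, filtering, epoching, averaging."""

import numpy as np
import pytest

import nirsloc as nl
from nirsloc.preprocess import DEFAULT_EXTINCTION, FilterSpec, mbll_convert


def _recording(data, probe, fs=13.3, events=()):
    return nl.Recording(
        data=data, fs_hz=fs, chromophore="oxy",
        channels=list(probe.channels)[: data.shape[0]], events=list(events),
    )


class TestMbll:
    def test_forward_inverse_round_trip(self, rng):
        E = np.array([DEFAULT_EXTINCTION[w] for w in (780, 805, 830)])
        L = 30.0
        dc = rng.normal(size=(2, 200))
        od = E @ dc * L
        oxy, deoxy, total = mbll_convert(od, pathlength_mm=L)
        np.testing.assert_allclose(oxy, dc[0], atol=1e-10)
        np.testing.assert_allclose(deoxy, dc[1], atol=1e-10)
        np.testing.assert_allclose(total, dc.sum(axis=0), atol=1e-10)

    def test_pure_oxy_change_recovered(self):
        E = np.array([DEFAULT_EXTINCTION[w] for w in (780, 805, 830)])
        od = (E @ np.array([[1.0], [0.0]])) * 30.0
        oxy, deoxy, _ = mbll_convert(np.tile(od, (1, 5)), pathlength_mm=30.0)
        np.testing.assert_allclose(oxy, 1.0, atol=1e-12)
        np.testing.assert_allclose(deoxy, 0.0, atol=1e-12)

    def test_zero_od_gives_zero_concentration(self):
        oxy, deoxy, total = mbll_convert(np.zeros((3, 10)))
        assert not oxy.any() and not deoxy.any() and not total.any()

    def test_rank_deficient_extinction_rejected(self):
        bad = {780: (1.0, 2.0), 805: (2.0, 4.0), 830: (0.5, 1.0)}
        with pytest.raises(np.linalg.LinAlgError):
            mbll_convert(np.zeros((3, 4)), extinction_table=bad)


class TestCar:
    def test_zero_mean_input_is_fixed_point(self, probe):
        x = np.vstack([np.sin(np.arange(100.0)), -np.sin(np.arange(100.0))])
        rec = _recording(x, probe)
        out = nl.car_filter(rec)
        np.testing.assert_allclose(out.data, x, atol=1e-14)

    def test_identical_channels_zeroed(self, probe):
        x = np.tile(np.arange(50.0), (20, 1))
        out = nl.car_filter(_recording(x, probe))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_column_means_vanish(self, probe, rng):
        out = nl.car_filter(_recording(rng.normal(size=(20, 500)), probe))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12

    def test_single_channel_rejected(self, probe):
        with pytest.raises(nl.ValidationError):
            nl.car_filter(_recording(np.zeros((1, 50)), probe))

    def test_removes_shared_global_component_exactly(self, probe, rng):
        base = rng.normal(size=(20, 600))
        g = rng.normal(size=600)
        rec_a = _recording(base, probe)
        rec_b = _recording(base + g[None, :], probe)
        np.testing.assert_allclose(
            nl.car_filter(rec_a).data, nl.car_filter(rec_b).data, atol=1e-12
        )


class TestBandpass:
    fs = 13.3

    def _sine(self, f, probe, dur=300.0):
        t = np.arange(0, dur, 1 / self.fs)
        return _recording(np.tile(np.sin(2 * np.pi * f * t), (20, 1)), probe)

    def test_cardiac_band_attenuated(self, probe):
        rec = self._sine(1.2, probe)
        out = nl.bandpass(rec)
        mid = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        ratio = np.sqrt(np.mean(out.data[0, mid] ** 2) / np.mean(rec.data[0, mid] ** 2))
        assert ratio < 0.01  # >= 40 dB

    def test_passband_preserved(self, probe):
        rec = self._sine(0.1, probe, dur=600.0)
        out = nl.bandpass(rec)
        mid = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        ratio = np.sqrt(np.mean(out.data[0, mid] ** 2) / np.mean(rec.data[0, mid] ** 2))
        assert 0.9 < ratio < 1.1  # within ~1 dB

    def test_dc_removed(self, probe):
        rec = _recording(np.full((20, 4000), 3.7), probe)
        out = nl.bandpass(rec)
        mid = slice(1000, 3000)
        assert np.abs(out.data[:, mid].mean()) < 1e-3

    def test_cutoff_above_nyquist_rejected(self, probe):
        rec = self._sine(0.1, probe)
        with pytest.raises(nl.ValidationError):
            nl.bandpass(rec, FilterSpec(low_pass_hz=7.0))

    def test_filter_commutes_with_segmentation(self, probe, rng):
        """Filtering continuous data then epoching == epoching pre-filtered data."""
        data = rng.normal(size=(20, 2000))
        events = [nl.Event(onset_s=30.0, location_deg=0, intensity_db=48),
                  nl.Event(onset_s=60.0, location_deg=90, intensity_db=58)]
        rec = _recording(data, probe, events=events)
        filtered = nl.bandpass(nl.car_filter(rec))
        tt = nl.segment(filtered, baseline="none")
        tt2 = nl.segment(nl.bandpass(nl.car_filter(_recording(data, probe, events=events))),
                         baseline="none")
        np.testing.assert_allclose(tt.data, tt2.data, atol=1e-12)


class TestSegment:
    def test_default_session_epoch_count_and_length(self, lateral_session):
        rec, _, _ = lateral_session
        tt = nl.segment(rec)
        assert tt.n_trials == 100
        assert tt.n_samples == 133  # round(10 s * 13.3 Hz)

    def test_constant_signal_zeroed_by_baseline(self, probe):
        rec = _recording(np.full((20, 600), 2.5), probe,
                         events=[nl.Event(onset_s=5.0, location_deg=0, intensity_db=48)])
        tt = nl.segment(rec, baseline="pre_stim_mean")
        np.testing.assert_allclose(tt.data, 0.0, atol=1e-14)

    def test_boundary_onset_accepted_then_rejected(self, probe):
        n = 600
        fs = 13.3
        ok_onset = (n - 133) / fs
        rec = _recording(np.zeros((20, n)), probe,
                         events=[nl.Event(onset_s=ok_onset, location_deg=0, intensity_db=48)])
        assert nl.segment(rec, baseline="none").n_trials == 1
        bad = _recording(np.zeros((20, n)), probe,
                         events=[nl.Event(onset_s=ok_onset + 1 / fs, location_deg=0,
                                          intensity_db=48)])
        with pytest.raises(nl.ValidationError, match="edge"):
            nl.segment(bad, baseline="none")


class TestRoiAverage:
    def test_single_channel_roi_passthrough(self, lateral_session, probe):
        rec, _, _ = lateral_session
        tt = nl.segment(rec)
        rt = nl.roi_average(tt, probe)
        # ROI 3 = channel 4 alone; ROI 10 = channel 19 alone
        np.testing.assert_allclose(rt.data[:, 2], tt.data[:, 3], atol=1e-12)
        np.testing.assert_allclose(rt.data[:, 9], tt.data[:, 18], atol=1e-12)

    def test_mean_of_members(self, probe):
        data = np.zeros((1, 20, 10))
        for const, ch in zip((1.0, 2.0, 3.0, 4.0), (1, 2, 5, 8)):
            data[0, ch - 1] = const
        tt = nl.TrialTensor(data=data, labels=[(0, 48)], fs_hz=13.3,
                            unit_kind="channel", unit_ids=list(range(1, 21)))
        rt = nl.roi_average(tt, probe)
        np.testing.assert_allclose(rt.data[0, 0], 2.5)

    def test_permutation_invariance(self, probe, rng):
        data = rng.normal(size=(3, 20, 40))
        tt = nl.TrialTensor(data=data, labels=[(0, 48)] * 3, fs_hz=13.3,
                            unit_kind="channel", unit_ids=list(range(1, 21)))
        perm = rng.permutation(20)
        tt_p = nl.TrialTensor(data=data[:, perm], labels=[(0, 48)] * 3, fs_hz=13.3,
                              unit_kind="channel", unit_ids=[int(p) + 1 for p in perm])
        np.testing.assert_allclose(nl.roi_average(tt, probe).data,
                                   nl.roi_average(tt_p, probe).data, atol=1e-12)


class TestGrandAverage:
    def _tensor(self, data, labels):
        return nl.TrialTensor(data=data, labels=labels, fs_hz=13.3,
                              unit_kind="roi", unit_ids=list(range(1, data.shape[1] + 1)))

    def test_identical_trials_have_zero_sem(self):
        data = np.tile(np.arange(12.0).reshape(1, 2, 6), (2, 1, 1))
        ga = nl.grand_average(self._tensor(data, [(0, 48)] * 2))
        mean, sem = ga[(0,)]
        np.testing.assert_allclose(sem, 0.0, atol=1e-14)
        np.testing.assert_allclose(mean, data[0])

    def test_mean_of_two_curves(self):
        data = np.stack([np.zeros((2, 6)), np.full((2, 6), 2.0)])
        ga = nl.grand_average(self._tensor(data, [(0, 48)] * 2))
        mean, _ = ga[(0,)]
        np.testing.assert_allclose(mean, 1.0)

    def test_monte_carlo_recovery(self, rng):
        truth = np.sin(np.linspace(0, np.pi, 50))
        data = truth[None, None, :] + rng.normal(0, 0.5, size=(1000, 1, 50))
        ga = nl.grand_average(self._tensor(data, [(0, 48)] * 1000))
        mean, sem = ga[(0,)]
        frac = np.mean(np.abs(mean[0] - truth) <= 3 * sem[0])
        assert frac >= 0.99

    def test_empty_condition_rejected(self):
        data = np.zeros((2, 1, 5))
        with pytest.raises(nl.ValidationError):
            nl.grand_average(self._tensor(data, [(0, 48), (90, 58)]))
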