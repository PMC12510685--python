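import numpy as np
import pytest

from dmrsmicro.synthetic import simulate_transients
from dmrsmicro.transients import (
    KurtosisFit,
    OutlierMask,
    TransientSet,
    combine_coils,
    compute_mup,
    correct_phase_freq,
    detect_outliers,
    fit_mup_dki,
    load_transients,
    powder_average,
    remove_water_svd,
    save_transients,
)

QUIET = dict(freq_jitter_sd=0.0, phase_jitter_sd=0.0, amp_jitter_sd=0.0, noise_sd=0.0)


def minimal_set(**kwargs):
    ts, truth = simulate_transients(
        tm=100.0, b_values=[0.035], n_directions=1, reps_per_b=(3,), seed=0, **kwargs
    )
    return ts, truth


class TestCoilCombination:
    def test_four_coils_combine_to_root_sum_square(self):
        ts, truth = minimal_set(n_coils=4, **QUIET)
        combined = combine_coils(ts, truth["water_ref"])
        single, _ = minimal_set(**QUIET)
        amp_expected = np.sqrt(np.sum(truth["coil_amps"] ** 2)) * np.abs(single.fids[0, 0])
        assert np.abs(combined.fids[0, 0]) == pytest.approx(amp_expected, rel=1e-6)

    def test_single_coil_passthrough_up_to_phase(self):
        ts, _ = minimal_set(**QUIET)
        wref = TransientSet(
            fids=ts.fids[:1] * np.exp(1j * 0.7), b=ts.b[:1],
            direction=ts.direction[:1], repetition=ts.repetition[:1],
        )
        out = combine_coils(ts, wref)
        np.testing.assert_allclose(np.abs(out.fids), np.abs(ts.fids), rtol=1e-12)

    def test_zero_signal_coil_gets_zero_weight(self):
        ts, truth = minimal_set(n_coils=3, **QUIET)
        wref = truth["water_ref"]
        wref.fids[:, 1, :] = 0.0
        dead_coil_noise = ts.fids.copy()
        dead_coil_noise[:, 1, :] = 1e6  # junk in the dead coil must not leak
        ts_dead = TransientSet(fids=dead_coil_noise, b=ts.b, direction=ts.direction,
                               repetition=ts.repetition)
        with pytest.warns(UserWarning):
            out = combine_coils(ts_dead, wref)
        assert np.all(np.isfinite(out.fids))
        assert np.abs(out.fids).max() < 1e4

    def test_missing_reference_rejected(self):
        ts, _ = minimal_set(n_coils=2, **QUIET)
        with pytest.raises(ValueError):
            combine_coils(ts, None)


class TestMup:
    def test_zero_spectrum(self):
        ts, _ = minimal_set(**QUIET)
        assert compute_mup(np.zeros(ts.n_points), ts.ppm_axis) == 0.0

    def test_constant_magnitude(self):
        ts, _ = minimal_set(**QUIET)
        assert compute_mup(np.full(ts.n_points, 3.0 + 0j), ts.ppm_axis) == pytest.approx(3.0)

    def test_matches_direct_window_mean(self):
        ts, _ = minimal_set(**QUIET)
        spec = ts.spectra()[0]
        sel = (ts.ppm_axis >= 1.9) & (ts.ppm_axis <= 4.5)
        direct = np.abs(spec[sel]).mean()
        assert compute_mup(spec, ts.ppm_axis) == pytest.approx(direct, rel=1e-9)

    def test_uncovered_window_rejected(self):
        ts, _ = minimal_set(**QUIET)
        with pytest.raises(ValueError):
            compute_mup(ts.spectra()[0], ts.ppm_axis, ppm_range=(-100.0, -90.0))


class TestMupKurtosisFit:
    def test_noiseless_self_consistency(self):
        b = np.array([0.035, 3.035, 6.0, 10.0, 20.0, 30.0])
        truth = KurtosisFit(D_app=0.4, K_app=1.0, m0=10.0)
        fit = fit_mup_dki(b, truth.predict(b))
        assert fit.D_app == pytest.approx(0.4, abs=1e-6)
        assert fit.K_app == pytest.approx(1.0, abs=1e-6)

    def test_monoexponential_gives_zero_kurtosis(self):
        b = np.array([0.035, 3.035, 6.0, 10.0])
        fit = fit_mup_dki(b, 5.0 * np.exp(-0.3 * b))
        assert fit.K_app == pytest.approx(0.0, abs=1e-9)

    def test_two_b_fallback_warns(self):
        with pytest.warns(UserWarning, match="monoexponential"):
            fit = fit_mup_dki(np.array([0.035, 3.035]), np.array([10.0, 5.0]))
        assert fit.K_app == 0.0

    def test_nonpositive_medians_rejected(self):
        with pytest.raises(ValueError):
            fit_mup_dki(np.array([0.0, 3.0, 6.0]), np.array([1.0, 0.0, 0.5]))


class TestOutlierDetection:
    def test_identical_mup_keeps_everything(self):
        m = np.full(24, 5.0)
        b = np.repeat([0.035, 6.0], 12)
        d = np.tile(np.repeat([0, 1], 6), 2)
        mask = detect_outliers(m, b, d)
        assert mask.keep.all()

    def test_single_low_transient_flagged(self):
        rng = np.random.default_rng(0)
        m = 10.0 + 0.05 * rng.standard_normal(10)
        m[4] = 5.0
        mask = detect_outliers(m, np.full(10, 0.035), np.zeros(10, dtype=int))
        assert not mask.keep[4]
        assert mask.keep.sum() == 9

    def test_injected_motion_corruption_recovered(self):
        ts, truth = simulate_transients(
            tm=100.0, b_values=[0.035, 3.035, 6.0, 10.0],
            n_directions=4, reps_per_b=(4, 4, 6, 6),
            corrupt={2: 0.4, 50: 0.4}, seed=3,
        )
        mup = compute_mup(ts.spectra(), ts.ppm_axis)
        mask = detect_outliers(mup, ts.b, ts.direction)
        assert not mask.keep[2] and not mask.keep[50]
        clean = np.setdiff1d(np.arange(ts.n_transients), [2, 50])
        assert np.mean(~mask.keep[clean]) <= 0.05

    def test_order_invariance(self):
        ts, _ = simulate_transients(
            tm=100.0, b_values=[0.035, 6.0], n_directions=2, reps_per_b=(4, 6),
            corrupt={1: 0.4}, seed=5,
        )
        mup = compute_mup(ts.spectra(), ts.ppm_axis)
        mask = detect_outliers(mup, ts.b, ts.direction)
        perm = np.random.default_rng(1).permutation(ts.n_transients)
        mask_p = detect_outliers(mup[perm], ts.b[perm], ts.direction[perm])
        np.testing.assert_array_equal(mask.keep[perm], mask_p.keep)

    def test_too_few_b0_transients_rejected(self):
        with pytest.raises(ValueError):
            detect_outliers(np.array([1.0, 1.0]), np.array([0.0, 3.0]), np.array([0, 0]))

    def test_mask_invariants(self):
        with pytest.raises(ValueError):
            OutlierMask(keep=np.ones(3, bool), m_up=np.ones(3), thresholds=np.array([1.0, np.inf, 1.0]))


class TestRegistration:
    def test_no_drift_recovers_null_shifts(self):
        ts, _ = simulate_transients(
            tm=100.0, b_values=[0.035], n_directions=2, reps_per_b=(5,),
            freq_jitter_sd=0.0, phase_jitter_sd=0.0, noise_sd=0.05, seed=0,
        )
        _, shifts, phases, ok = correct_phase_freq(ts)
        assert np.all(np.abs(shifts) < 0.05)
        assert ok.all()

    def test_injected_frequency_shift_recovered(self):
        ts, _ = simulate_transients(
            tm=100.0, b_values=[0.035], n_directions=2, reps_per_b=(5,),
            freq_jitter_sd=0.0, phase_jitter_sd=0.0, noise_sd=0.02, seed=1,
        )
        t = ts.time_axis
        ts.fids[3] = ts.fids[3] * np.exp(1j * 2 * np.pi * 5.0 * t)
        _, shifts, _, _ = correct_phase_freq(ts)
        assert shifts[3] == pytest.approx(-5.0, abs=0.1)

    def test_injected_phase_recovered(self):
        ts, _ = simulate_transients(
            tm=100.0, b_values=[0.035], n_directions=2, reps_per_b=(5,),
            freq_jitter_sd=0.0, phase_jitter_sd=0.0, noise_sd=0.02, seed=2,
        )
        ts.fids[1] = ts.fids[1] * np.exp(1j * np.deg2rad(30.0))
        _, _, phases, _ = correct_phase_freq(ts)
        assert np.rad2deg(phases[1]) == pytest.approx(-30.0, abs=1.0)

    def test_alignment_tightens_frequency_spread(self):
        ts, truth = simulate_transients(
            tm=100.0, b_values=[0.035], n_directions=4, reps_per_b=(5,),
            freq_jitter_sd=7.0, phase_jitter_sd=20.0, noise_sd=0.05, seed=3,
        )
        aligned, shifts, _, _ = correct_phase_freq(ts)
        residual = truth["freq_shifts"] + shifts
        assert np.std(residual - residual.mean()) <= 0.5


class TestPowderAverage:
    def test_identical_transients_mean_is_member(self):
        ts, _ = minimal_set(**QUIET)
        out = powder_average(ts)
        np.testing.assert_allclose(out[0.035], ts.fids[0], rtol=1e-12)

    def test_amplitude_mean(self):
        ts, _ = minimal_set(**QUIET)
        fids = np.stack([ts.fids[0], 3.0 * ts.fids[0]])
        ts2 = TransientSet(fids=fids, b=ts.b[:2], direction=ts.direction[:2],
                           repetition=ts.repetition[:2])
        np.testing.assert_allclose(powder_average(ts2)[0.035], 2.0 * ts.fids[0], rtol=1e-12)

    def test_masked_transient_excluded(self):
        ts, _ = minimal_set(**QUIET)
        mask = OutlierMask(keep=np.array([True, False, True]), m_up=np.ones(3),
                           thresholds=np.zeros(3))
        out = powder_average(ts, mask)
        np.testing.assert_allclose(out[0.035], ts.fids[[0, 2]].mean(axis=0), rtol=1e-12)

    def test_empty_condition_missing_not_fabricated(self):
        ts, _ = minimal_set(**QUIET)
        mask = OutlierMask(keep=np.zeros(3, bool), m_up=np.ones(3), thresholds=np.zeros(3))
        assert powder_average(ts, mask) == {}

    def test_permutation_invariance(self):
        ts, _ = simulate_transients(tm=100.0, b_values=[0.035, 6.0], n_directions=2,
                                    reps_per_b=(3, 3), seed=7)
        perm = np.random.default_rng(0).permutation(ts.n_transients)
        ts_p = TransientSet(fids=ts.fids[perm], b=ts.b[perm], direction=ts.direction[perm],
                            repetition=ts.repetition[perm])
        a, b_ = powder_average(ts), powder_average(ts_p)
        for key in a:
            np.testing.assert_allclose(a[key], b_[key], rtol=1e-12)


class TestWaterRemoval:
    def _pair(self, water_amp):
        kw = dict(tm=100.0, b_values=[0.035], n_directions=1, reps_per_b=(1,), seed=3, **QUIET)
        ts_w, _ = simulate_transients(water_amp=water_amp, **kw)
        ts_0, _ = simulate_transients(water_amp=0.0, **kw)
        return ts_w, ts_0

    @staticmethod
    def _mag(fid):
        return np.abs(np.fft.fftshift(np.fft.fft(fid)))

    def test_no_water_passthrough(self):
        _, ts_0 = self._pair(0.0)
        out = remove_water_svd(ts_0.fids[0], ts_0)
        assert np.max(np.abs(out - ts_0.fids[0])) / np.abs(ts_0.fids[0]).max() < 1e-6

    def test_water_suppressed_metabolites_preserved(self):
        ts_w, ts_0 = self._pair(20.0)
        clean = remove_water_svd(ts_w.fids[0], ts_w)
        ppm = ts_w.ppm_axis
        wsel = (ppm >= 4.2) & (ppm <= 5.3)
        msel = (ppm >= 1.9) & (ppm <= 4.5)
        water_before = self._mag(ts_w.fids[0])[wsel].max()
        water_after = self._mag(clean)[wsel].max()
        assert water_after <= 0.01 * water_before
        truth_mag = self._mag(ts_0.fids[0])
        err = np.max(np.abs(self._mag(clean)[msel] - truth_mag[msel]))
        assert err <= 0.01 * truth_mag[msel].max()

    def test_pure_water_removed_to_noise(self):
        kw = dict(tm=100.0, b_values=[0.035], n_directions=1, reps_per_b=(1,),
                  metabolite_amps={}, mm_amp=0.0, seed=3, **QUIET)
        ts, _ = simulate_transients(water_amp=20.0, **kw)
        clean = remove_water_svd(ts.fids[0], ts)
        assert np.linalg.norm(clean) <= 1e-3 * np.linalg.norm(ts.fids[0])


class TestPersistence:
    def test_hdf5_roundtrip(self, tmp_path):
        ts, _ = minimal_set(noise_sd=0.1)
        path = str(tmp_path / "transients.h5")
        save_transients(path, ts)
        back = load_transients(path)
        np.testing.assert_array_equal(back.fids, ts.fids)
        np.testing.assert_array_equal(back.b, ts.b)
        assert back.sw == ts.sw and back.tm == ts.tm


class TestEndToEnd:
    def test_powder_amplitude_recovery_with_corruption_and_drift(self):
        """Full pipeline: outlier mask + alignment + powder average recovers
        the known metabolite amplitudes within a few percent."""
        errs = []
        for seed in range(5):
            ts, truth = simulate_transients(
                tm=100.0, b_values=[0.035], n_directions=4, reps_per_b=(6,),
                freq_jitter_sd=4.0, phase_jitter_sd=15.0, noise_sd=0.1,
                corrupt={3: 0.4}, seed=seed,
            )
            mup = compute_mup(ts.spectra(), ts.ppm_axis)
            mask = detect_outliers(mup, ts.b, ts.direction)
            assert not mask.keep[3]
            aligned, *_ = correct_phase_freq(ts, mask)
            avg = powder_average(aligned, mask)[0.035]
            # zero-padded spectra so peak height is insensitive to the
            # sub-bin position of the aligned common frequency frame
            pad = 8 * ts.n_points
            spec = np.abs(np.fft.fftshift(np.fft.fft(avg, pad)))
            ppm = ts.ref_ppm + np.fft.fftshift(np.fft.fftfreq(pad, d=ts.dt)) / ts.f0
            # tNAA singlet height against the clean noiseless reference
            ref_ts, _ = simulate_transients(
                tm=100.0, b_values=[0.035], n_directions=1, reps_per_b=(1,),
                seed=0, **QUIET,
            )
            ref = np.abs(np.fft.fftshift(np.fft.fft(ref_ts.fids[0], pad)))
            sel = (ppm > 1.95) & (ppm < 2.07)
            errs.append(abs(spec[sel].max() / ref[sel].max() - 1.0))
        assert np.median(errs) <= 0.03


class TestQCReport:
    def test_counts_per_condition(self):
        ts, _ = simulate_transients(
            tm=100.0, b_values=[0.035, 6.0], n_directions=2, reps_per_b=(4, 4),
            corrupt={1: 0.4}, seed=0,
        )
        from dmrsmicro.transients import qc_report

        mup = compute_mup(ts.spectra(), ts.ppm_axis)
        mask = detect_outliers(mup, ts.b, ts.direction)
        rep = qc_report(ts, mask)
        assert rep["n_transients"] == 16
        assert sum(c["kept"] + c["discarded"] for c in rep["conditions"]) == 16
        assert rep["total_discarded"] >= 1
        import json
        json.dumps(rep)  # JSON-serializable
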