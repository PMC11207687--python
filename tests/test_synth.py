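"""Synthetic generator: Bessel-ratio oracle, synchrony control, dataset
shape and determinism."""

import itertools

import numpy as np
import pytest

from vimsplv.connectivity import instantaneous_phase, plv_matrix, plv_pair, segment
from vimsplv.preprocess import bandpass_filter, preprocess_recording
from vimsplv.recording import infer_region
from vimsplv.synth import (
    SynthConfig,
    expected_plv,
    expected_plv_pair,
    generate_recording,
    generate_session,
    sample_phase_segments,
)

GAMMA = (("gamma", 30.0, 45.0, 37.5, 4.0),)
FLAT_REGIONS = {r: 1.0 for r in
                ("frontal", "temporal", "central", "parietal", "occipital")}


def gamma_cfg(kappa0, seed=0, **kw):
    """Single-band config with state-independent concentration kappa0 and no
    regional structure, for calibration tests."""
    return SynthConfig(
        n_subjects=1,
        bands=GAMMA,
        kappa={"gamma": (kappa0, kappa0, kappa0)},
        region_multipliers=FLAT_REGIONS,
        noise_sd=0.0,
        amp_jitter=0.0,
        seed=seed,
        **kw,
    )


def measured_gamma_plv(rec, reref=True):
    """Mean off-diagonal PLV over all 3-s segments in the gamma band."""
    if reref:
        clean = preprocess_recording(rec)
    else:
        from vimsplv.preprocess import downsample

        clean = downsample(bandpass_filter(rec, 0.5, 45.0), 1024.0)
    g = bandpass_filter(clean, 30.0, 45.0)
    mats = [plv_matrix(instantaneous_phase(s, g.rate))
            for s in segment(g.data, g.rate)]
    return np.mean([m.mean_offdiagonal() for m in mats])


class TestExpectedPLV:
    def test_zero_concentration_gives_zero(self):
        assert expected_plv(0.0) == 0.0

    def test_saturates_to_one(self):
        assert expected_plv(1e8) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_increasing(self):
        ks = np.linspace(0.0, 20.0, 50)
        vals = [expected_plv(k) for k in ks]
        assert np.all(np.diff(vals) > 0)

    def test_pair_form_factorizes(self):
        assert expected_plv_pair(2.0, 2.0) == pytest.approx(expected_plv(2.0))
        r2 = np.sqrt(expected_plv(2.0))
        r5 = np.sqrt(expected_plv(5.0))
        assert expected_plv_pair(2.0, 5.0) == pytest.approx(r2 * r5)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            expected_plv(-1.0)
        with pytest.raises(ValueError):
            SynthConfig(kappa={"gamma": (-1.0, 0.0, 0.0)})

    def test_kappa2_matches_monte_carlo_phase_model(self):
        """(I1(k)/I0(k))^2 against the jitter model itself at N=3072."""
        rng = np.random.default_rng(11)
        vals = [plv_pair(ph[0], ph[1])
                for ph in sample_phase_segments(2.0, 200, rng=rng)]
        assert np.mean(vals) == pytest.approx(expected_plv(2.0), rel=0.05)


class TestGeneratedSignal:
    def test_jitter_off_gives_perfect_synchrony(self):
        """kappa -> inf: all channels share one phase trajectory; pipeline
        PLV is 1 within 1e-3."""
        rec = generate_recording(gamma_cfg(1e8), 0, "VIMS_0")
        assert measured_gamma_plv(rec, reref=False) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_jitter_phase_model_hits_sampling_floor(self):
        """kappa = 0 with one independent draw per sample: mean PLV equals
        the N-sample estimator floor sqrt(pi)/(2 sqrt(N)) ~ 0.016."""
        rng = np.random.default_rng(13)
        vals = [plv_pair(ph[0], ph[1])
                for ph in sample_phase_segments(0.0, 300, rng=rng)]
        floor = np.sqrt(np.pi) / (2 * np.sqrt(3072))
        assert np.mean(vals) == pytest.approx(floor, rel=0.10)

    def test_uniform_jitter_signal_route_collapses(self):
        """kappa = 0 through the signal route: synchrony collapses to the
        few-effective-samples floor of the slow-jitter design, far below any
        coupled condition."""
        rec = generate_recording(gamma_cfg(0.0), 0, "VIMS_0")
        assert measured_gamma_plv(rec, reref=False) < 0.5

    def test_intermediate_kappa_within_monte_carlo_band(self):
        """Through band-pass + Hilbert, the per-segment sample PLV sits near
        the finite-sample expectation sqrt(p^2 + (1-p^2)/M) of the
        mean-phasor modulus, with p the population (Bessel-ratio) PLV and
        M = 6 independent jitter knots per 3-s segment (2 Hz knot rate)."""
        for kappa in (2.0, 8.0):
            rec = generate_recording(gamma_cfg(kappa, seed=4), 0, "VIMS_0")
            measured = measured_gamma_plv(rec, reref=False)
            p = expected_plv(kappa)
            m_eff = 3.0 * 2.0
            predicted = np.sqrt(p ** 2 + (1 - p ** 2) / m_eff)
            assert measured == pytest.approx(predicted, rel=0.15)

    def test_pipeline_plv_monotone_in_kappa(self):
        """Paired per-segment mean PLV is ordered across kappa levels for
        nearly every segment (the synchrony dial works through the full
        preprocessing chain, including average re-reference)."""
        per_level = []
        for kappa in (0.5, 2.0, 8.0):
            rec = generate_recording(gamma_cfg(kappa, seed=2), 0, "VIMS_0")
            clean = preprocess_recording(rec)
            g = bandpass_filter(clean, 30.0, 45.0)
            vals = [plv_matrix(instantaneous_phase(s, g.rate)).mean_offdiagonal()
                    for s in segment(g.data, g.rate)]
            per_level.append(vals)
        lo, mid, hi = (np.array(v) for v in per_level)
        frac_ordered = np.mean((mid > lo) & (hi > mid))
        assert frac_ordered >= 0.95

    def test_regional_multipliers_create_predicted_gradient(self):
        """Frontal pairs (multiplier 1.25) must out-synchronize occipital
        pairs (0.8) by roughly the oracle-predicted margin."""
        cfg = SynthConfig(n_subjects=1, bands=GAMMA,
                          kappa={"gamma": (3.0, 3.0, 3.0)},
                          noise_sd=0.0, amp_jitter=0.0, seed=6)
        rec = generate_recording(cfg, 0, "VIMS_0")
        clean = preprocess_recording(rec)
        g = bandpass_filter(clean, 30.0, 45.0)
        mats = [plv_matrix(instantaneous_phase(s, g.rate)).values
                for s in segment(g.data, g.rate)]
        mean_mat = np.mean(mats, axis=0)
        regions = [infer_region(lab) for lab in rec.labels]

        def region_mean(region):
            idx = [i for i, r in enumerate(regions) if r == region]
            pairs = [mean_mat[i, j] for i, j in itertools.combinations(idx, 2)]
            return np.mean(pairs)

        def biased(p, m_eff=6.0):
            return np.sqrt(p ** 2 + (1 - p ** 2) / m_eff)

        measured_gap = region_mean("frontal") - region_mean("occipital")
        oracle_gap = (biased(expected_plv(3.0 * 1.25))
                      - biased(expected_plv(3.0 * 0.8)))
        assert measured_gap > 0
        assert measured_gap == pytest.approx(oracle_gap, rel=0.5)

    def test_native_rate_and_duration(self):
        rec = generate_recording(gamma_cfg(1.0), 0, "VIMS_0")
        assert rec.rate == 2048.0
        assert rec.n_samples == 60 * 2048
        assert rec.n_channels == 52


class TestDatasetShape:
    def test_one_subject_yields_60_matrices(self):
        from vimsplv.pipeline import build_datasets

        ds = build_datasets(gamma_cfg(2.0), bands=("gamma",))["gamma"]
        assert len(ds) == 1 * 3 * 20
        assert ds.matrices.shape == (60, 52, 52)
        states, counts = np.unique(ds.states, return_counts=True)
        assert list(states) == ["VIMS_0", "VIMS_1", "VIMS_2"]
        assert counts.tolist() == [20, 20, 20]

    def test_fixed_seed_regenerates_bit_identically(self):
        cfg = gamma_cfg(2.0, seed=9)
        a, _ = generate_session(cfg, 0)
        b, _ = generate_session(cfg, 0)
        assert np.array_equal(a.data, b.data)

    def test_different_subjects_differ(self):
        cfg = gamma_cfg(2.0, seed=9)
        a, _ = generate_session(cfg, 0)
        b, _ = generate_session(cfg, 1)
        assert not np.array_equal(a.data, b.data)

    def test_session_report_times_inside_recording(self):
        rec, times = generate_session(gamma_cfg(1.0), 0)
        assert times["t2"] <= rec.duration
        assert times["t1"] - 30 >= times["rest_start"] + 60
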