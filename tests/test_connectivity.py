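"""PLV connectivity: window extraction, segmentation, phase, PLV and
topology thresholding."""

import itertools
import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vimsplv.connectivity import (
    PhaseSeries,
    PLVMatrix,
    average_matrices,
    extract_state_windows,
    instantaneous_phase,
    plv_matrix,
    plv_pair,
    segment,
    threshold_topology,
)
from vimsplv.recording import EEGRecording

FS = 1024.0


def brute_force_plv(phase_x, phase_y):
    """Independent oracle: the PLV formula as an explicit per-sample loop."""
    acc = 0.0 + 0.0j
    for a, b in zip(phase_x, phase_y):
        acc += complex(np.cos(a - b), np.sin(a - b))
    return abs(acc) / len(phase_x)


# -- state-window extraction -------------------------------------------------

class TestExtractStateWindows:
    def rec(self, dur=500.0):
        return EEGRecording(np.zeros((2, int(dur * FS))), FS, ("A", "B"))

    def test_protocol_window_placement(self):
        w = extract_state_windows(self.rec(), {"rest_start": 0, "t1": 300, "t2": 400})
        sec = lambda ab: (ab[0] / FS, ab[1] / FS)
        assert sec(w["VIMS_0"]) == (0.0, 60.0)
        assert sec(w["VIMS_1"]) == (270.0, 330.0)
        assert sec(w["VIMS_2"]) == (340.0, 400.0)

    def test_light_report_too_early_names_state(self):
        with pytest.raises(ValueError, match="VIMS_1"):
            extract_state_windows(self.rec(), {"rest_start": 0, "t1": 20, "t2": 400})

    def test_heavy_report_too_early_names_state(self):
        with pytest.raises(ValueError, match="VIMS_2"):
            extract_state_windows(self.rec(), {"rest_start": 0, "t1": 300, "t2": 50})

    def test_overlapping_windows_logged_not_fatal(self, caplog):
        with caplog.at_level(logging.WARNING):
            extract_state_windows(self.rec(), {"rest_start": 0, "t1": 380, "t2": 400})
        assert any("overlap" in m for m in caplog.messages)


# -- segmentation ------------------------------------------------------------

class TestSegment:
    def test_60s_window_gives_20_segments_of_3072(self, rng):
        x = rng.normal(size=(52, int(60 * FS)))
        segs = segment(x, FS, 3.0)
        assert len(segs) == 20
        assert all(s.shape == (52, 3072) for s in segs)

    def test_short_signal_gives_empty_list(self, rng):
        assert segment(rng.normal(size=(2, int(2 * FS))), FS, 3.0) == []

    def test_trailing_remainder_dropped_in_order(self):
        x = np.arange(int(7 * FS))[None, :]
        segs = segment(x, FS, 3.0)
        assert len(segs) == 2
        assert segs[0][0, 0] == 0
        assert segs[1][0, 0] == 3 * 3072 / 3  # second segment starts at 3 s
        assert segs[1][0, -1] == 2 * 3072 - 1


# -- instantaneous phase -----------------------------------------------------

class TestInstantaneousPhase:
    def central(self, x):
        n = len(x)
        return x[n // 10 : -n // 10]

    def test_pure_tone_phase_slope(self):
        t = np.arange(3072) / FS
        ph = instantaneous_phase(np.sin(2 * np.pi * 10 * t), FS).phase[0]
        slope = np.diff(self.central(np.unwrap(ph))) * FS
        assert np.allclose(slope.mean(), 2 * np.pi * 10, rtol=0.01)

    def test_cos_leads_sin_by_half_pi(self):
        t = np.arange(3072) / FS
        pc = instantaneous_phase(np.cos(2 * np.pi * 10 * t), FS).phase[0]
        ps = instantaneous_phase(np.sin(2 * np.pi * 10 * t), FS).phase[0]
        diff = np.angle(np.exp(1j * (pc - ps)))
        assert np.allclose(self.central(diff), np.pi / 2, atol=0.02)

    def test_zero_channel_gets_zero_phase_and_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            ph = instantaneous_phase(np.zeros((2, 100)), FS)
        assert np.all(ph.phase[0] == 0) and np.all(ph.phase[1] == 0)
        assert any("all-zero" in m for m in caplog.messages)

    def test_phases_wrapped_and_finite(self, rng):
        ph = instantaneous_phase(rng.normal(size=(4, 512)), FS).phase
        assert np.isfinite(ph).all()
        assert (ph > -np.pi - 1e-12).all() and (ph <= np.pi + 1e-12).all()


# -- PLV ---------------------------------------------------------------------

class TestPLVPair:
    def test_identical_series_give_exactly_one(self, rng):
        p = rng.uniform(-np.pi, np.pi, 3072)
        assert plv_pair(p, p) == 1.0

    def test_constant_offset_gives_one(self, rng):
        p = rng.uniform(-np.pi, np.pi, 3072)
        assert plv_pair(p, p + 1.234) == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_alternation_cancels(self):
        x = np.zeros(100)
        y = np.where(np.arange(100) % 2 == 0, 0.0, np.pi)
        assert plv_pair(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_independent_phases_match_rayleigh_mean(self, rng):
        """|mean of N random unit phasors| has mean ~ sqrt(pi)/(2 sqrt(N))."""
        n, draws = 3072, 1000
        vals = [
            plv_pair(rng.uniform(-np.pi, np.pi, n), rng.uniform(-np.pi, np.pi, n))
            for _ in range(draws)
        ]
        expect = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert np.mean(vals) == pytest.approx(expect, rel=0.10)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            a = rng.uniform(-np.pi, np.pi, 200)
            b = rng.uniform(-np.pi, np.pi, 200)
            assert plv_pair(a, b) == pytest.approx(brute_force_plv(a, b), abs=1e-12)

    def test_sample_size_scaling_follows_inverse_sqrt(self, rng):
        """Expected PLV of independent phases falls by sqrt(2) when N doubles."""
        means = []
        for n in (512, 1024):
            vals = [
                plv_pair(rng.uniform(-np.pi, np.pi, n),
                         rng.uniform(-np.pi, np.pi, n))
                for _ in range(800)
            ]
            means.append(np.mean(vals))
        assert means[0] / means[1] == pytest.approx(np.sqrt(2), rel=0.15)

    def test_amplitude_invariance_via_phase_extraction(self, rng):
        """PLV is a phase-only statistic: rescaling a channel's raw signal
        leaves it unchanged."""
        x = rng.normal(size=3072)
        y = rng.normal(size=3072)
        p1 = instantaneous_phase(np.vstack([x, y]), FS)
        p2 = instantaneous_phase(np.vstack([7.3 * x, 0.01 * y]), FS)
        a = plv_pair(p1.phase[0], p1.phase[1])
        b = plv_pair(p2.phase[0], p2.phase[1])
        assert a == pytest.approx(b, abs=1e-9)

    @given(offset=st.floats(-np.pi, np.pi))
    def test_common_offset_invariance(self, offset):
        rng = np.random.default_rng(7)
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        assert plv_pair(a + offset, b + offset) == pytest.approx(
            plv_pair(a, b), abs=1e-12
        )

    def test_rejects_mismatched_lengths_and_empty(self):
        with pytest.raises(ValueError):
            plv_pair(np.zeros(5), np.zeros(4))
        with pytest.raises(ValueError):
            plv_pair(np.zeros(0), np.zeros(0))


class TestPLVMatrix:
    def test_52_channel_matrix_shape_and_invariants(self, rng):
        ph = PhaseSeries(rng.uniform(-np.pi, np.pi, (52, 3072)), FS)
        m = plv_matrix(ph)
        assert m.values.shape == (52, 52)
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 1.0)
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_identical_channels_give_all_ones(self):
        p = np.linspace(-np.pi, np.pi, 100)
        m = plv_matrix(PhaseSeries(np.vstack([p, p]), FS))
        assert np.allclose(m.values, 1.0)

    def test_independent_channels_near_rayleigh_floor(self, rng):
        ph = PhaseSeries(rng.uniform(-np.pi, np.pi, (30, 3072)), FS)
        m = plv_matrix(ph)
        off = m.values[np.triu_indices(30, k=1)]
        assert off.mean() == pytest.approx(np.sqrt(np.pi) / (2 * np.sqrt(3072)),
                                           rel=0.10)

    def test_agrees_with_pairwise_calls(self, rng):
        ph = PhaseSeries(rng.uniform(-np.pi, np.pi, (5, 300)), FS)
        m = plv_matrix(ph)
        for i, j in itertools.combinations(range(5), 2):
            assert m.values[i, j] == pytest.approx(
                plv_pair(ph.phase[i], ph.phase[j]), abs=1e-12
            )

    @given(seed=st.integers(0, 1000))
    def test_randomized_symmetry_and_unit_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        m = plv_matrix(PhaseSeries(rng.uniform(-np.pi, np.pi, (6, 64)), FS))
        assert np.array_equal(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 1.0)
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0


class TestAverageMatrices:
    def mat(self, values, band="gamma", state="VIMS_0"):
        return PLVMatrix(values, band=band, state=state)

    def test_mean_of_identical_matrices_is_identity_case(self, rng):
        v = plv_matrix(PhaseSeries(rng.uniform(-np.pi, np.pi, (4, 100)), FS)).values
        out = average_matrices([self.mat(v), self.mat(v)])
        np.testing.assert_allclose(out[("gamma", "VIMS_0")].values, v)

    def test_mean_of_ones_and_zeros_off_diagonal(self):
        ones = np.ones((3, 3))
        zeros = np.eye(3)
        out = average_matrices([self.mat(ones), self.mat(zeros)])
        v = out[("gamma", "VIMS_0")].values
        assert np.all(np.diag(v) == 1.0)
        off = v[np.triu_indices(3, k=1)]
        assert np.allclose(off, 0.5)

    def test_grouping_by_band_and_state(self):
        mats = [
            self.mat(np.eye(3), "gamma", "VIMS_0"),
            self.mat(np.eye(3), "gamma", "VIMS_1"),
            self.mat(np.eye(3), "delta", "VIMS_0"),
        ]
        out = average_matrices(mats)
        assert set(out) == {("gamma", "VIMS_0"), ("gamma", "VIMS_1"),
                            ("delta", "VIMS_0")}
        assert out[("delta", "VIMS_0")].band == "delta"


class TestThresholdTopology:
    def full_matrix(self, n, off):
        v = np.full((n, n), off)
        np.fill_diagonal(v, 1.0)
        return PLVMatrix(v)

    def test_all_above_threshold_keeps_every_edge(self):
        topo = threshold_topology(self.full_matrix(52, 0.6), 0.55)
        assert topo.n_edges == 52 * 51 // 2 == 1326

    def test_all_below_threshold_keeps_none(self):
        assert threshold_topology(self.full_matrix(52, 0.5), 0.55).n_edges == 0

    def test_boundary_kept_at_geq(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.9
        v[0, 2] = v[2, 0] = 0.55
        v[1, 2] = v[2, 1] = 0.2
        topo = threshold_topology(PLVMatrix(v), 0.55)
        assert topo.n_edges == 2
        weights = sorted(w for *_, w in topo.edges)
        assert weights == [0.55, 0.9]

    def test_proportional_mode_keeps_density_fraction(self, rng):
        ph = PhaseSeries(rng.uniform(-np.pi, np.pi, (10, 200)), FS)
        topo = threshold_topology(plv_matrix(ph), 0.2, proportional=True)
        assert topo.n_edges == round(0.2 * 45)

    def test_labeled_csv_roundtrip(self, tmp_path, rng):
        from vimsplv.connectivity import PLVMatrix as PM

        ph = PhaseSeries(rng.uniform(-np.pi, np.pi, (3, 200)), FS)
        ph.labels = ("Fp1", "Cz", "O1")
        m = plv_matrix(ph, band="gamma")
        m.save_csv(tmp_path / "m.csv")
        back = PM.from_csv(tmp_path / "m.csv", band="gamma")
        np.testing.assert_allclose(back.values, m.values, atol=1e-12)
        assert back.labels == ("Fp1", "Cz", "O1")

    def test_graph_export_roundtrip(self, tmp_path):
        import networkx as nx

        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.9
        m = PLVMatrix(v, labels=("Fp1", "Cz", "O1"))
        topo = threshold_topology(m, 0.55)
        topo.save_graphml(tmp_path / "g.graphml")
        g = nx.read_graphml(tmp_path / "g.graphml")
        assert set(g.nodes) == {"Fp1", "Cz", "O1"}
        assert g.has_edge("Fp1", "Cz")
        topo.save_edgelist_csv(tmp_path / "e.csv")
        assert (tmp_path / "e.csv").read_text().startswith("source,target,weight")
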