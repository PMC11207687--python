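"""Synthetic phase-coupled EEG with a closed-form synchrony oracle.

Each channel is a sum of narrowband oscillations plus white noise:

    x_k(t) = sum_b A_b * cos(Phi_b(t) + eps_kb(t)) + w_k(t)

where Phi_b is a phase trajectory shared by all channels (band-centre
carrier with a slow random frequency wander) and eps_kb is per-channel von
Mises phase jitter with concentration kappa(state, band) scaled by a
per-region multiplier.  Because the mean resultant length of a von Mises
deviate is the Bessel ratio R(kappa) = I1(kappa)/I0(kappa), the population
PLV between two channels with concentrations k1, k2 is R(k1)*R(k2) —
an analytic ground truth for every pipeline stage.

The jitter is piecewise-constant at a slow knot rate (default 2 Hz, i.e.
roughly 1 Hz bandwidth) so that the imposed synchrony survives band-pass
filtering and Hilbert phase extraction; zero-order hold preserves the von
Mises marginal exactly, which keeps the Bessel oracle valid.  Signals are
generated at the 2048 Hz native rate so the downsampling stage is always
exercised.  For estimator calibration, ``sample_phase_segments`` exposes the
same jitter model directly in the phase domain with one independent draw per
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import i0e, i1e

from .preprocess import exclude_channels
from .recording import (
    BIOSEMI64_LABELS,
    DEFAULT_EXCLUDED_CHANNELS,
    EEGRecording,
    REGIONS,
    STATES,
    infer_region,
)

__all__ = [
    "SynthConfig",
    "expected_plv",
    "expected_plv_pair",
    "generate_recording",
    "generate_session",
    "generate_dataset",
    "sample_phase_segments",
    "SESSION_REPORT_TIMES",
]

#: Generator bands: (name, lo, hi, carrier Hz, amplitude uV).
_GEN_BANDS = (
    ("delta", 0.5, 4.0, 2.25, 20.0),
    ("theta", 4.0, 8.0, 6.0, 10.0),
    ("alpha", 8.0, 14.0, 11.0, 8.0),
    ("beta", 15.0, 30.0, 22.5, 5.0),
    ("gamma", 30.0, 45.0, 37.5, 4.0),
)

#: Default per-band, per-state von Mises concentrations.  Synchrony is
#: highest in delta and lowest in gamma, and drops as sickness deepens, with
#: the largest relative between-state contrast in the high-frequency bands.
_DEFAULT_KAPPA = {
    "delta": (8.0, 7.0, 6.0),
    "theta": (6.0, 5.2, 4.4),
    "alpha": (5.0, 4.2, 3.4),
    "beta": (3.5, 2.3, 1.4),
    "gamma": (3.0, 1.5, 0.7),
}

#: Frontal/temporal channels couple more strongly than posterior ones.
_DEFAULT_REGION_MULTIPLIERS = {
    "frontal": 1.25,
    "temporal": 1.1,
    "central": 1.0,
    "parietal": 0.9,
    "occipital": 0.8,
}

#: Session timeline (seconds): 60 s rest from 0, light-sickness report at
#: t1 = 92 (window 62-122), heavy-sickness report at t2 = 184 (window
#: 124-184, after which the stimulus stops).  2-s guard gaps keep the three
#: 60-s analysis windows disjoint while the recording stays continuous.
SESSION_REPORT_TIMES = {"rest_start": 0.0, "t1": 92.0, "t2": 184.0}
_SESSION_DURATION = 184.0
_STATE_SPANS = {"VIMS_0": (0.0, 60.0), "VIMS_1": (62.0, 122.0), "VIMS_2": (124.0, 184.0)}


def _default_labels(n_channels: int) -> tuple:
    rec = EEGRecording(
        np.zeros((64, 1)), 2048.0, BIOSEMI64_LABELS
    )
    labels = exclude_channels(rec, DEFAULT_EXCLUDED_CHANNELS).labels
    if n_channels == len(labels):
        return labels
    if n_channels <= len(BIOSEMI64_LABELS):
        return BIOSEMI64_LABELS[:n_channels]
    raise ValueError(f"no default montage with {n_channels} channels")


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped generator settings.

    Defaults emulate the acquisition: 25 subjects, 52 retained channels,
    2048 Hz native sampling (analysed at 1024 Hz), 60 s per state and the
    five physiological bands (the 'full' band emerges from their sum).
    """

    n_subjects: int = 25
    n_channels: int = 52
    native_rate: float = 2048.0
    duration_per_state: float = 60.0
    kappa: Mapping[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_KAPPA))
    region_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_MULTIPLIERS)
    )
    bands: tuple = _GEN_BANDS
    amp_jitter: float = 0.2
    noise_sd: float = 2.0
    knot_rate: float = 2.0
    freq_wander_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for band, ks in self.kappa.items():
            if any(k < 0 for k in ks):
                raise ValueError(f"kappa must be >= 0, got {ks} for band {band!r}")
        if any(m < 0 for m in self.region_multipliers.values()):
            raise ValueError("region multipliers must be >= 0")
        if abs(self.duration_per_state * self.native_rate
               - round(self.duration_per_state * self.native_rate)) > 1e-9:
            raise ValueError("duration x rate must be integral")

    @classmethod
    def null(cls, **kwargs) -> "SynthConfig":
        """State-independent coupling: no class signal anywhere (negative
        control; a classifier must score at chance)."""
        kappa = {b: (k0, k0, k0) for b, (k0, _, _) in _DEFAULT_KAPPA.items()}
        return cls(kappa=kappa, **kwargs)

    def labels(self) -> tuple:
        return _default_labels(self.n_channels)


# ---------------------------------------------------------------------------
# oracle
# ---------------------------------------------------------------------------

def expected_plv(kappa: float) -> float:
    """Population PLV of two channels with equal concentration:
    (I1(kappa)/I0(kappa))^2.  0 at kappa=0, -> 1 as kappa -> inf."""
    return expected_plv_pair(kappa, kappa)


def expected_plv_pair(kappa_x: float, kappa_y: float) -> float:
    """Population PLV R(kx) * R(ky) for unequal channel concentrations."""
    if kappa_x < 0 or kappa_y < 0:
        raise ValueError("kappa must be >= 0")
    rx = float(i1e(kappa_x) / i0e(kappa_x))
    ry = float(i1e(kappa_y) / i0e(kappa_y))
    return rx * ry


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _subject_rng(cfg: SynthConfig, subject: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, int(subject)]))


def _carrier_phase(rng, n, rate, f_c, lo, hi, wander_sd) -> np.ndarray:
    """Shared band phase: carrier frequency with a slow, clipped random walk."""
    n_knots = int(np.ceil(n / rate)) + 1
    steps = rng.normal(0.0, wander_sd, n_knots)
    wander = np.clip(np.cumsum(steps), -0.3 * (hi - lo) / 2, 0.3 * (hi - lo) / 2)
    t_knots = np.arange(n_knots) * rate
    freq = f_c + np.interp(np.arange(n), t_knots, wander)
    phase0 = rng.uniform(0.0, 2 * np.pi)
    return phase0 + 2 * np.pi * np.cumsum(freq) / rate


def _zoh_jitter(rng, kappas, n, rate, knot_rate) -> np.ndarray:
    """(channels, n) piecewise-constant von Mises jitter, one concentration
    per channel."""
    per = max(1, int(round(rate / knot_rate)))
    n_knots = int(np.ceil(n / per))
    knots = np.stack([rng.vonmises(0.0, max(k, 1e-12), n_knots) for k in kappas])
    return np.repeat(knots, per, axis=1)[:, :n]


def _kappa_timeline(cfg: SynthConfig, band: str, n_knots: int, per: int,
                    rate: float, state: "str | None") -> np.ndarray:
    """Per-knot base concentration, following the session's state timeline
    (or constant, for a single-state recording)."""
    ks = cfg.kappa.get(band)
    if ks is None:
        return np.zeros(n_knots)
    if state is not None:
        return np.full(n_knots, ks[STATES.index(state)])
    t = (np.arange(n_knots) + 0.5) * per / rate
    out = np.full(n_knots, ks[0], dtype=float)
    for s, (a, b) in _STATE_SPANS.items():
        sel = (t >= a) & (t < b)
        out[sel] = ks[STATES.index(s)]
    # guard gaps: carry the upcoming state's concentration
    gap = (t >= 60.0) & (t < 62.0)
    out[gap] = ks[1]
    gap = (t >= 122.0) & (t < 124.0)
    out[gap] = ks[2]
    return out


def _generate(cfg: SynthConfig, subject: int, duration: float,
              state: "str | None") -> EEGRecording:
    rate = cfg.native_rate
    n = int(round(duration * rate))
    rng = _subject_rng(cfg, subject)
    labels = cfg.labels()
    mults = np.array([
        cfg.region_multipliers.get(infer_region(lab), 1.0) for lab in labels
    ])
    data = np.zeros((cfg.n_channels, n), dtype=np.float32)
    per = max(1, int(round(rate / cfg.knot_rate)))
    n_knots = int(np.ceil(n / per))
    for name, lo, hi, f_c, amp in cfg.bands:
        phi = _carrier_phase(rng, n, rate, f_c, lo, hi, cfg.freq_wander_sd)
        base = _kappa_timeline(cfg, name, n_knots, per, rate, state)
        # fixed per-channel phase offsets, equally spaced on the circle: they
        # leave every pairwise PLV unchanged (constant phase differences) but
        # cancel in the across-channel mean, so the whole-brain average
        # reference does not subtract the shared oscillator (a crude stand-in
        # for the spatial phase gradients of real scalp EEG)
        beta = 2 * np.pi * rng.permutation(cfg.n_channels) / cfg.n_channels
        # knot draws: concentration varies over time and across channels
        knots = np.empty((cfg.n_channels, n_knots))
        for k in range(cfg.n_channels):
            kk = np.maximum(base * mults[k], 1e-12)
            knots[k] = rng.vonmises(np.zeros(n_knots), kk)
        eps = np.repeat(knots, per, axis=1)[:, :n]
        amps = amp * (1.0 + rng.uniform(-cfg.amp_jitter, cfg.amp_jitter,
                                        cfg.n_channels))
        data += (amps[:, None] * np.cos(phi[None, :] + beta[:, None] + eps)
                 ).astype(np.float32)
        del eps, knots
    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, data.shape).astype(np.float32)
    return EEGRecording(data, rate, labels)


def generate_recording(cfg: SynthConfig, subject: int, state: str) -> EEGRecording:
    """One 60-s single-state recording at the native rate."""
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    return _generate(cfg, subject, cfg.duration_per_state, state)


def generate_session(cfg: SynthConfig, subject: int):
    """A continuous per-subject session covering all three states.

    Returns (recording, report_times); the report times reproduce the
    protocol's bookkeeping (rest onset, light-sickness report, heavy-sickness
    report) so the recording flows through the same window-extraction path
    as real data.
    """
    rec = _generate(cfg, subject, _SESSION_DURATION, None)
    return rec, dict(SESSION_REPORT_TIMES)


def generate_dataset(cfg: SynthConfig):
    """Yield (subject, recording, report_times) for the whole cohort.

    A generator, so that only one subject's session is in memory at a time;
    the default cohort produces n_subjects x 3 states x 20 segments PLV
    matrices per band once run through the pipeline.
    """
    for subject in range(cfg.n_subjects):
        rec, times = generate_session(cfg, subject)
        yield subject, rec, times


# ---------------------------------------------------------------------------
# phase-domain calibration route
# ---------------------------------------------------------------------------

def sample_phase_segments(
    kappa: float,
    n_segments: int,
    n_samples: int = 3072,
    n_channels: int = 2,
    rate: float = 1024.0,
    rng: "np.random.Generator | int | None" = None,
):
    """Phase-domain draws from the jitter model: per channel, phase =
    shared carrier ramp + i.i.d. von Mises jitter, one draw per sample.

    This is the generator's phase model with the jitter correlation time
    shrunk to a single sample — the regime in which the sample PLV over
    ``n_samples`` points is an essentially unbiased estimate of the
    population value ``expected_plv(kappa)``.  Used to calibrate the PLV
    estimator against the Bessel-ratio oracle.  Yields (channels, samples)
    phase arrays, wrapped to (-pi, pi].
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(rng)
    t = np.arange(n_samples) / rate
    for _ in range(n_segments):
        carrier = 2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi)
        eps = rng.vonmises(0.0, max(kappa, 1e-12), (n_channels, n_samples))
        phase = np.angle(np.exp(1j * (carrier[None, :] + eps)))
        yield phase
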