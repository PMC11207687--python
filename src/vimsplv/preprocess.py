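"""Preprocessing: channel exclusion, zero-phase filtering, downsampling,
average re-reference and band decomposition.

All filters are 6th-order Butterworth applied forward-backward
(``sosfiltfilt``), i.e. zero-phase: the phase-locking value downstream is a
phase statistic, so filters must not introduce phase distortion.  Filters are
always applied to whole recordings, never to 3-s segments, so segment edges
carry no filter transients.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .recording import BandDefinition, EEGRecording

__all__ = [
    "exclude_channels",
    "bandpass_filter",
    "notch_filter",
    "downsample",
    "rereference_average",
    "band_decompose",
    "remove_artifacts_ica",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)

_FILTER_ORDER = 6  # meets the 60 Hz -> <5% RMS stop-band contract under filtfilt


def exclude_channels(rec: EEGRecording, bad: "list[str] | tuple[str, ...]") -> EEGRecording:
    """Drop the named channels, preserving the order of the survivors.

    Matching is case-insensitive (electrode lists in print often vary the
    case of e.g. ``Fp2``/``FP2``).  An unknown name raises ``KeyError``
    naming the offending channel.
    """
    lower = {lab.lower(): i for i, lab in enumerate(rec.labels)}
    bad_idx = set()
    for name in bad:
        if name.lower() not in lower:
            raise KeyError(f"cannot exclude unknown channel {name!r}")
        bad_idx.add(lower[name.lower()])
    keep = [i for i in range(rec.n_channels) if i not in bad_idx]
    labels = tuple(rec.labels[i] for i in keep)
    regions = {lab: rec.regions[lab] for lab in labels}
    return EEGRecording(rec.data[keep], rec.rate, labels, regions)


def _sos_filter(rec: EEGRecording, sos: np.ndarray) -> EEGRecording:
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.with_data(out)


def bandpass_filter(rec: EEGRecording, lo: float, hi: float) -> EEGRecording:
    """Zero-phase Butterworth band-pass between ``lo`` and ``hi`` Hz."""
    nyq = rec.rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz is not below the Nyquist rate {nyq} Hz")
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    sos = signal.butter(_FILTER_ORDER, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    return _sos_filter(rec, sos)


def notch_filter(rec: EEGRecording, lo: float = 49.0, hi: float = 51.0) -> EEGRecording:
    """Zero-phase Butterworth band-stop (default 49-51 Hz, mains interference)."""
    nyq = rec.rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz is not below the Nyquist rate {nyq} Hz")
    sos = signal.butter(_FILTER_ORDER, [lo, hi], btype="bandstop", fs=rec.rate, output="sos")
    return _sos_filter(rec, sos)


def downsample(rec: EEGRecording, target_rate: float = 1024.0) -> EEGRecording:
    """Reduce the sampling rate by an integer factor.

    An anti-alias zero-phase low-pass at 0.9x the target Nyquist precedes
    decimation.  Non-integer ratios (including upsampling) are refused.
    """
    ratio = rec.rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1 - 1e-9:
        raise ValueError(
            f"rate {rec.rate} Hz is not an integer multiple of target {target_rate} Hz"
        )
    factor = int(round(ratio))
    if factor == 1:
        return rec
    cutoff = 0.9 * (target_rate / 2.0)
    sos = signal.butter(8, cutoff, btype="lowpass", fs=rec.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.with_data(filtered[:, ::factor], rate=target_rate)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the whole-brain average: subtract the across-channel
    mean at every sample.  Idempotent."""
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def band_decompose(
    rec: EEGRecording, bands: "list[BandDefinition] | tuple[BandDefinition, ...]"
) -> "dict[str, EEGRecording]":
    """One zero-phase band-passed copy of the recording per band.

    The ``full`` band (0.5-45 Hz) is just the broadband-filtered signal; it
    goes through the same band-pass code path.
    """
    return {band.name: bandpass_filter(rec, band.lo, band.hi) for band in bands}


def remove_artifacts_ica(rec: EEGRecording) -> EEGRecording:
    """Artifact-removal hook (EMG/EOG via ICA in the original protocol).

    Intentionally a no-op here: the synthetic generator produces no ocular or
    muscular artifacts, so there is nothing to remove.  The hook keeps the
    pipeline stage order explicit and reserves the interface for real data.
    """
    logger.info("ICA artifact removal: no-op hook (no artifacts modelled)")
    return rec


def preprocess_recording(
    rec: EEGRecording,
    bad_channels: "tuple[str, ...] | list[str]" = (),
    bandpass: tuple[float, float] = (0.5, 45.0),
    notch: tuple[float, float] = (49.0, 51.0),
    target_rate: float = 1024.0,
) -> EEGRecording:
    """The standard preprocessing chain, in protocol order.

    exclude bad channels -> 0.5-45 Hz band-pass -> 49-51 Hz notch ->
    downsample to 1024 Hz -> whole-brain average re-reference -> ICA hook.
    Band decomposition is a separate step (``band_decompose``).
    """
    if bad_channels:
        rec = exclude_channels(rec, bad_channels)
    rec = bandpass_filter(rec, *bandpass)
    rec = notch_filter(rec, *notch)
    rec = downsample(rec, target_rate)
    rec = rereference_average(rec)
    rec = remove_artifacts_ica(rec)
    if not np.isfinite(rec.data).all():
        raise ValueError("non-finite samples after preprocessing")
    return rec
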