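"""Core domain containers for multichannel EEG.

The study system is a 64-channel BioSemi recording (10-20 placement,
2048 Hz native) whose channels fall into five scalp regions: frontal,
temporal, central, parietal and occipital.  After exclusion of twelve
noisy electrodes, 52 channels remain and every connectivity matrix in
the pipeline is indexed in their (file-header) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "EEGRecording",
    "BandDefinition",
    "StateWindows",
    "CANONICAL_BANDS",
    "BIOSEMI64_LABELS",
    "DEFAULT_EXCLUDED_CHANNELS",
    "REGIONS",
    "infer_region",
    "STATES",
]

#: The three graded motion-sickness states: resting, light and heavy sickness.
STATES = ("VIMS_0", "VIMS_1", "VIMS_2")

#: Scalp regions used to group electrodes.
REGIONS = ("frontal", "temporal", "central", "parietal", "occipital")

#: 64-channel BioSemi cap in its native header order (10-20 extension names).
BIOSEMI64_LABELS = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: Electrodes with poor signal quality in the study, excluded for all subjects.
DEFAULT_EXCLUDED_CHANNELS = (
    "PO4", "O2", "PO8", "P10", "TP8", "F6",
    "FP2", "FPz", "POz", "P2", "P1", "PO3",
)


def infer_region(label: str) -> str:
    """Map a 10-20 electrode label to one of the five scalp regions."""
    u = label.strip()
    for prefix, region in (
        ("Fp", "frontal"), ("AF", "frontal"),
        ("FT", "temporal"), ("FC", "central"),
        ("F", "frontal"),
        ("TP", "temporal"), ("T", "temporal"),
        ("CP", "central"), ("C", "central"),
        ("PO", "occipital"), ("P", "parietal"),
        ("O", "occipital"), ("I", "occipital"),
    ):
        if u.upper().startswith(prefix.upper()):
            return region
    raise ValueError(f"cannot infer a scalp region for channel label {label!r}")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band as a half-open interval in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r} requires 0 < lo < hi, got lo={self.lo}, hi={self.hi}"
            )


#: The six analysis bands: five physiological rhythms plus the broadband signal.
CANONICAL_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
    BandDefinition("full", 0.5, 45.0),
)


@dataclass
class EEGRecording:
    """A channels x samples block of EEG in microvolts.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), microvolts.
    rate
        Sampling rate in Hz.
    labels
        Ordered channel names; must be unique and match ``data``'s row count.
    regions
        Optional channel -> scalp-region map; inferred from labels if omitted.
    """

    data: np.ndarray
    rate: float
    labels: tuple[str, ...]
    regions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.regions:
            regions = {}
            for lab in self.labels:
                try:
                    regions[lab] = infer_region(lab)
                except ValueError:
                    regions[lab] = "unknown"  # toy/non-10-20 labels
            self.regions = regions

    # -- convenience -------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.rate

    def with_data(self, data: np.ndarray, rate: float | None = None) -> "EEGRecording":
        """Copy of this recording with new samples (same channels)."""
        return replace(self, data=data, rate=self.rate if rate is None else rate)

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


@dataclass(frozen=True)
class StateWindows:
    """Per-state 60-s analysis windows as [start, end) sample indices.

    VIMS_0 is the first 60 s of rest, VIMS_1 straddles the light-sickness
    report (30 s either side) and VIMS_2 is the 60 s immediately before the
    heavy-sickness report, after which the stimulus was stopped.
    """

    windows: Mapping[str, tuple[int, int]]
    rate: float

    def __post_init__(self) -> None:
        for state, (start, end) in self.windows.items():
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            if end - start != round(60 * self.rate):
                raise ValueError(
                    f"{state} window spans {(end - start) / self.rate:g} s, expected 60 s"
                )
            if start < 0:
                raise ValueError(f"{state} window starts before the recording")

    def __getitem__(self, state: str) -> tuple[int, int]:
        return self.windows[state]

    def items(self):
        return self.windows.items()
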