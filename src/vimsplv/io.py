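"""Reading and writing EEG recordings and state-timestamp sidecars.

Reading EDF/BDF goes through MNE (`mne.io.read_raw_bdf` / `read_raw_edf`),
taking channel labels verbatim from the file header.  Writing uses a
minimal BioSemi BDF (24-bit) writer implemented here, since no EDF/BDF
*writer* is available as a library dependency; round-trips are validated
against the MNE reader in the test suite.

State timestamps travel in a small tab-separated sidecar with columns
``subject``, ``state``, ``onset_s`` (states: VIMS_0 row marks the rest
onset, VIMS_1 the light-sickness report, VIMS_2 the heavy-sickness report).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .recording import EEGRecording

__all__ = ["write_bdf", "read_recording", "write_sidecar", "read_sidecar"]

_DIG_MAX = 2 ** 23 - 1
_DIG_MIN = -(2 ** 23)
_PHYS_MAX = 32768.0  # microvolts; gain ~= 256 digital units / uV


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_bdf(path: "str | Path", rec: EEGRecording) -> Path:
    """Write a recording as a 24-bit BioSemi BDF file.

    The record duration is 1 s; the recording is zero-padded up to a whole
    number of records.  Physical range is fixed at +/-32768 uV (resolution
    ~0.004 uV), which comfortably covers scalp EEG.
    """
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("BDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1-s record
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    if np.abs(rec.data).max(initial=0.0) > _PHYS_MAX:
        raise ValueError("samples exceed the +/-32768 uV physical range")

    header = bytearray()
    header += b"\xffBIOSEMI"
    header += _field("vimsplv synthetic subject", 80)
    header += _field("vimsplv recording", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field((n_ch + 1) * 256, 8)
    header += _field("24BIT", 44)
    header += _field(n_rec, 8)
    header += _field(1, 8)
    header += _field(n_ch, 4)
    for lab in rec.labels:
        header += _field(lab, 16)
    header += b"".join(_field("active electrode", 80) for _ in range(n_ch))
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(int(-_PHYS_MAX), 8) for _ in range(n_ch))
    header += b"".join(_field(int(_PHYS_MAX), 8) for _ in range(n_ch))
    header += b"".join(_field(_DIG_MIN, 8) for _ in range(n_ch))
    header += b"".join(_field(_DIG_MAX, 8) for _ in range(n_ch))
    header += b"".join(_field("none", 80) for _ in range(n_ch))
    header += b"".join(_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))
    assert len(header) == (n_ch + 1) * 256

    scale = (_DIG_MAX - _DIG_MIN) / (2 * _PHYS_MAX)
    padded = np.zeros((n_ch, n_rec * spr), dtype=np.float64)
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(np.round(padded * scale), _DIG_MIN, _DIG_MAX).astype("<i4")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]  # (n_ch, spr)
            raw = np.ascontiguousarray(block).view(np.uint8).reshape(n_ch, spr, 4)
            fh.write(raw[:, :, :3].tobytes())
    return path


def read_recording(path: "str | Path") -> EEGRecording:
    """Read an EDF or BDF file into an ``EEGRecording`` (microvolts)."""
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    elif suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG file format {suffix!r} (need .bdf or .edf)")
    data_uv = raw.get_data() * 1e6  # MNE stores volts
    return EEGRecording(data_uv, float(raw.info["sfreq"]), tuple(raw.ch_names))


def write_sidecar(path: "str | Path", subject, report_times: Mapping[str, float]) -> Path:
    """Write the state-timestamp sidecar for one subject."""
    path = Path(path)
    rows = [
        ("VIMS_0", report_times.get("rest_start", 0.0)),
        ("VIMS_1", report_times["t1"]),
        ("VIMS_2", report_times["t2"]),
    ]
    lines = ["subject\tstate\tonset_s"]
    lines += [f"{subject}\t{state}\t{onset:g}" for state, onset in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_sidecar(path: "str | Path") -> "tuple[str, dict[str, float]]":
    """Read a sidecar back into (subject, report_times)."""
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    if header != ["subject", "state", "onset_s"]:
        raise ValueError(f"unrecognized sidecar header {header!r}")
    subject = None
    times: dict[str, float] = {}
    key = {"VIMS_0": "rest_start", "VIMS_1": "t1", "VIMS_2": "t2"}
    for line in lines[1:]:
        subj, state, onset = line.split("\t")
        subject = subj
        times[key[state]] = float(onset)
    if subject is None or set(times) != {"rest_start", "t1", "t2"}:
        raise ValueError("sidecar must contain one row per state")
    return subject, times
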