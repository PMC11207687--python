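"""Phase-locking-value (PLV) functional connectivity.

For two channels with instantaneous phases phi_x(t), phi_y(t), the PLV over a
segment of N samples is

    PLV = | (1/N) * sum_n exp(j * (phi_x(n) - phi_y(n))) |

i.e. the modulus of the time-averaged unit phasor of the phase difference:
1 for perfect phase locking, ~0 for independent phases.  Phases come from the
analytic (Hilbert-transform) signal of each band-passed channel.  Each
state's 60-s window is cut into non-overlapping 3-s segments and one
channels x channels PLV matrix is computed per segment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import hilbert

from .recording import EEGRecording, STATES, StateWindows

__all__ = [
    "PhaseSeries",
    "PLVMatrix",
    "NetworkTopology",
    "ConnectivityDataset",
    "extract_state_windows",
    "segment",
    "instantaneous_phase",
    "plv_pair",
    "plv_matrix",
    "average_matrices",
    "threshold_topology",
]

logger = logging.getLogger(__name__)


@dataclass
class PhaseSeries:
    """Instantaneous phase per channel, radians wrapped to (-pi, pi]."""

    phase: np.ndarray  # (channels, samples)
    rate: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase)
        if not np.isfinite(self.phase).all():
            raise ValueError("phases must be finite")


@dataclass
class PLVMatrix:
    """A symmetric channels x channels PLV matrix with its provenance labels."""

    values: np.ndarray
    band: str = ""
    state: str = ""
    subject: "int | str" = -1
    segment: int = -1
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLV matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("PLV matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-9:
            raise ValueError("PLV entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def mean_offdiagonal(self) -> float:
        n = self.n_channels
        iu = np.triu_indices(n, k=1)
        return float(self.values[iu].mean())

    def save_csv(self, path: "str | Path") -> None:
        """Labeled CSV export (channel names as row/column headers)."""
        import pandas as pd

        labels = self.labels or tuple(str(i) for i in range(self.n_channels))
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: "str | Path", **labels) -> "PLVMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), labels=tuple(df.columns), **labels)


@dataclass
class NetworkTopology:
    """Thresholded undirected connectivity graph (i < j, no self-loops)."""

    edges: list  # (label_i, label_j, weight)
    threshold: float
    labels: tuple[str, ...] = ()

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self):
        """As a networkx Graph (weights on edges, region on nodes)."""
        import networkx as nx
        from .recording import infer_region

        g = nx.Graph()
        for lab in self.labels:
            g.add_node(lab, region=infer_region(lab))
        for i, j, w in self.edges:
            g.add_edge(i, j, weight=float(w))
        return g

    def save_edgelist_csv(self, path: "str | Path") -> None:
        import pandas as pd

        pd.DataFrame(self.edges, columns=["source", "target", "weight"]).to_csv(
            path, index=False
        )

    def save_graphml(self, path: "str | Path") -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), path)


@dataclass
class ConnectivityDataset:
    """A stack of PLV matrices with class labels: the classifier's input.

    ``matrices`` has shape (n, C, C); ``states`` holds the per-matrix VIMS
    state name, ``subjects``/``segments`` the provenance indices.
    """

    matrices: np.ndarray
    states: np.ndarray        # str array of VIMS_0/1/2
    subjects: np.ndarray
    segments: np.ndarray
    band: str = ""
    labels: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.matrices.shape[0]

    def class_labels(self, n_classes: int = 3) -> np.ndarray:
        """Integer targets: ternary keeps the three states; binary merges the
        two sickness states (resting=0 vs motion sickness=1)."""
        idx = np.array([STATES.index(s) for s in self.states])
        if n_classes == 3:
            return idx
        if n_classes == 2:
            return (idx > 0).astype(int)
        raise ValueError("n_classes must be 2 or 3")

    @classmethod
    def from_matrices(cls, mats: Sequence[PLVMatrix]) -> "ConnectivityDataset":
        if not mats:
            raise ValueError("no matrices given")
        bands = {m.band for m in mats}
        if len(bands) != 1:
            raise ValueError(f"matrices span several bands: {sorted(bands)}")
        return cls(
            matrices=np.stack([m.values for m in mats]),
            states=np.array([m.state for m in mats]),
            subjects=np.array([m.subject for m in mats]),
            segments=np.array([m.segment for m in mats]),
            band=bands.pop(),
            labels=mats[0].labels,
        )

    def save(self, prefix: "str | Path") -> None:
        """Persist as a flat float array plus a JSON sidecar."""
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.matrices.astype(np.float32))
        sidecar = {
            "band": self.band,
            "n": len(self),
            "n_channels": int(self.matrices.shape[1]),
            "states": self.states.tolist(),
            "subjects": [int(s) for s in self.subjects],
            "segments": [int(s) for s in self.segments],
            "channel_order": list(self.labels),
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, prefix: "str | Path") -> "ConnectivityDataset":
        prefix = Path(prefix)
        mats = np.load(prefix.with_suffix(".npy")).astype(float)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            matrices=mats,
            states=np.array(meta["states"]),
            subjects=np.array(meta["subjects"]),
            segments=np.array(meta["segments"]),
            band=meta["band"],
            labels=tuple(meta["channel_order"]),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_state_windows(
    rec: EEGRecording,
    report_times: Mapping[str, float],
    window_s: float = 60.0,
) -> StateWindows:
    """Locate the per-state 60-s analysis windows.

    ``report_times`` carries ``rest_start`` (onset of the resting baseline,
    seconds), ``t1`` (light-sickness report) and ``t2`` (heavy-sickness
    report, when the stimulus was stopped).  Windows: VIMS_0 = first 60 s of
    rest; VIMS_1 = [t1-30, t1+30); VIMS_2 = [t2-60, t2).
    """
    rate = rec.rate
    n = rec.n_samples
    rest = float(report_times.get("rest_start", 0.0))
    t1 = float(report_times["t1"])
    t2 = float(report_times["t2"])
    half = window_s / 2.0
    spans = {
        "VIMS_0": (rest, rest + window_s),
        "VIMS_1": (t1 - half, t1 + half),
        "VIMS_2": (t2 - window_s, t2),
    }
    if t2 - t1 < half:
        logger.warning(
            "light- and heavy-sickness windows overlap (t2 - t1 = %.1f s < %.1f s)",
            t2 - t1, half,
        )
    windows = {}
    for state, (a, b) in spans.items():
        ia, ib = round(a * rate), round(b * rate)
        if ia < 0 or ib > n:
            raise ValueError(
                f"{state} window [{a:g}, {b:g}) s exceeds the recording bounds "
                f"[0, {n / rate:g}) s"
            )
        windows[state] = (ia, ib)
    return StateWindows(windows, rate)


def segment(window_signal: np.ndarray, rate: float, win_len: float = 3.0) -> list:
    """Cut a (channels, samples) block into non-overlapping ``win_len``-s
    segments in temporal order; a trailing remainder is discarded."""
    x = np.asarray(window_signal)
    seg_samples = round(win_len * rate)
    n_seg = x.shape[-1] // seg_samples
    return [x[..., i * seg_samples:(i + 1) * seg_samples] for i in range(n_seg)]


def instantaneous_phase(seg: np.ndarray, rate: float = 1024.0) -> PhaseSeries:
    """Phase of the analytic (Hilbert-transform) signal, per channel.

    An identically-zero channel has no defined phase; by convention its phase
    is 0 and a warning is logged rather than failing mid-pipeline.
    """
    x = np.atleast_2d(np.asarray(seg, dtype=float))
    zero = np.all(x == 0.0, axis=-1)
    phase = np.zeros_like(x)
    if (~zero).any():
        analytic = hilbert(x[~zero], axis=-1)
        phase[~zero] = np.angle(analytic)
    if zero.any():
        logger.warning(
            "instantaneous_phase: %d all-zero channel(s); phase set to 0", zero.sum()
        )
    return PhaseSeries(phase, rate)


def plv_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """PLV between two phase series: |mean exp(j*(phi_x - phi_y))|."""
    px = np.asarray(phase_x, dtype=float).ravel()
    py = np.asarray(phase_y, dtype=float).ravel()
    if px.shape != py.shape:
        raise ValueError("phase series must have equal length")
    if px.size < 1:
        raise ValueError("need at least one sample")
    return float(np.abs(np.exp(1j * (px - py)).mean()))


def plv_matrix(
    phases: PhaseSeries,
    band: str = "",
    state: str = "",
    subject: "int | str" = -1,
    seg_index: int = -1,
) -> PLVMatrix:
    """All-pairs PLV for one segment: symmetric, unit diagonal.

    Computed as |Z Z^H| / N with Z the channels x samples matrix of unit
    phasors, which is exactly the pairwise formula vectorised.
    """
    z = np.exp(1j * phases.phase)
    n = z.shape[-1]
    vals = np.abs(z @ z.conj().T) / n
    vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(vals, 1.0)
    return PLVMatrix(vals, band=band, state=state, subject=subject,
                     segment=seg_index, labels=phases.labels)


def average_matrices(
    matrices: Iterable[PLVMatrix],
    group_by: tuple = ("band", "state"),
) -> "dict[tuple, PLVMatrix]":
    """Element-wise mean of PLV matrices within each (band, state, ...) group.

    Averaging runs across subjects and segments inside each group, matching
    the construction of the per-band, per-state average connectivity matrix.
    """
    groups: dict[tuple, list[PLVMatrix]] = {}
    for m in matrices:
        key = tuple(getattr(m, g) for g in group_by)
        groups.setdefault(key, []).append(m)
    out = {}
    for key, ms in groups.items():
        mean = np.mean([m.values for m in ms], axis=0)
        np.fill_diagonal(mean, 1.0)
        kwargs = dict(zip(group_by, key))
        out[key] = PLVMatrix(
            mean,
            band=kwargs.get("band", ""),
            state=kwargs.get("state", ""),
            subject=kwargs.get("subject", -1),
            labels=ms[0].labels,
        )
    return out


def threshold_topology(
    matrix: PLVMatrix,
    threshold: float = 0.55,
    proportional: bool = False,
) -> NetworkTopology:
    """Keep undirected edges with PLV >= threshold (diagonal excluded).

    With ``proportional=True`` the threshold is instead read as an edge
    *density*: the strongest ``threshold`` fraction of the C*(C-1)/2 possible
    edges is kept (an alternative reading of a "sparsity threshold").
    """
    v = matrix.values
    n = matrix.n_channels
    labels = matrix.labels or tuple(str(i) for i in range(n))
    iu, ju = np.triu_indices(n, k=1)
    w = v[iu, ju]
    if proportional:
        if not (0.0 <= threshold <= 1.0):
            raise ValueError("proportional threshold must be in [0, 1]")
        k = int(round(threshold * w.size))
        keep = np.zeros(w.size, dtype=bool)
        if k > 0:
            keep[np.argsort(w)[::-1][:k]] = True
    else:
        keep = w >= threshold
    edges = [(labels[i], labels[j], float(x))
             for i, j, x in zip(iu[keep], ju[keep], w[keep])]
    return NetworkTopology(edges=edges, threshold=threshold, labels=labels)
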