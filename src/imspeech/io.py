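"""Containers, run configuration, and file I/O.

EEG recordings travel as :class:`MultichannelRecording` (channels x samples,
microvolts).  On disk they are either EDF (16-bit, written by the in-package
EDF+ writer, read back through MNE) or a delimited numeric matrix with a JSON
sidecar carrying the sampling rate and channel labels.  Feature tables are CSV
with a fixed column contract: ordered feature names, then ``label``,
``participant``, ``trial``, ``segment``.

Feature-column ordering is channel-major, then sub-band (IMF 2..9 or WPD node
0..7), then statistic (mean, absolute mean, variance, standard deviation,
skewness, kurtosis).  Sample indexing is 0-based with half-open windows
``[start, start + length)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("imspeech")

#: statistic names in vectorization order
STAT_NAMES = ("mean", "absmean", "var", "std", "skew", "kurt")


class FormatError(ValueError):
    """Raised for malformed or unrecognized on-disk data."""


class ConfigurationError(ValueError):
    """Raised for invalid run or simulation configuration."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MultichannelRecording:
    """A multichannel sampled signal (channels x samples, microvolts).

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
    sampling_rate : float
        Sampling rate in Hz, strictly positive.
    channel_labels : list of str
        Unique labels, one per channel.
    annotations : list of (onset_sample, duration_samples, label), optional
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    annotations: list[tuple[int, int, str]] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise FormatError("data must be a 2-D (channels x samples) array")
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class Trial:
    """A labelled imagery epoch with its provenance."""

    recording: MultichannelRecording
    label: int
    participant: int
    session: int
    trial_id: int


@dataclass
class Segment:
    """A windowed sub-epoch of a trial.

    ``lineage`` is (participant, session, trial_id, segment_index); the trial
    id uniquely identifies the parent trial within a participant.
    """

    data: np.ndarray
    label: int
    lineage: tuple[int, int, int, int]
    sampling_rate: float

    @property
    def participant(self) -> int:
        return self.lineage[0]

    @property
    def trial_id(self) -> int:
        return self.lineage[2]

    @property
    def segment_index(self) -> int:
        return self.lineage[3]


@dataclass
class FeatureVector:
    """Ordered feature values with aligned names, label, and lineage.

    ``lineage`` is (participant, trial_id, segment_index) — the columns the
    feature CSV carries beside ``label``.
    """

    values: np.ndarray
    names: list[str]
    label: int
    lineage: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.names) != self.values.size:
            raise FormatError("feature names and values misaligned")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Defaults follow the study protocol wherever it states a value: resample to
    250 Hz, 0.1 Hz high-pass, 59-61 Hz order-4 Butterworth notch, 1 s windows
    with 0.5 s step, NA-MEMD with IMFs 2-9 used for features, MRF-CNN trained
    with Adam at lr 0.001 for 2000 iterations, 10x10-fold cross-validation.
    Values the protocol leaves open (q, K, noise power, sift thresholds,
    branch kernels past the first, batch size) are literature-standard or
    desk-scale choices, all exposed here.
    """

    # preprocessing
    target_rate: float = 250.0
    highpass_cutoff: float = 0.1
    notch_band: tuple[float, float] = (59.0, 61.0)
    notch_order: int = 4
    window: float = 1.0
    step: float = 0.5
    amplitude_threshold: float = 100.0  # stand-in automatic rejection, µV

    # decomposition
    method: str = "namemd"  # or "wpd"
    q: int = 1
    noise_power_fraction: float = 0.05
    n_directions: int = 64
    max_imfs: int = 9
    sift_thresholds: tuple[float, float, float] = (0.05, 0.5, 0.05)
    max_sift_iterations: int = 100
    wpd_level: int = 3
    wavelet: str = "db2"

    # features
    use_bands: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9)
    standardize: bool = True

    # classifier
    classifier: str = "mrf"
    learning_rate: float = 1e-3
    iterations: int = 2000
    batch_size: int = 32
    branch_kernels: tuple[int, ...] = (20, 40, 60, 80)
    second_kernel: int = 10
    filters: tuple[int, int] = (8, 16)
    pool: int = 4
    fc_units: int = 32
    relu_before_pool: bool = True
    knn_neighbors: int = 4

    # evaluation
    k: int = 10
    repeats: int = 10
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(fields)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for name, f in fields.items():
            if name in raw and isinstance(f.default, tuple):
                raw[name] = tuple(raw[name])
        return cls(**raw)


# ---------------------------------------------------------------------------
# recordings on disk
# ---------------------------------------------------------------------------

_DELIMITED = {".csv", ".tsv", ".txt"}


def read_recording(path: str | Path) -> MultichannelRecording:
    """Read an EDF file or a delimited matrix (+ JSON sidecar) as a recording.

    EDF sample values are converted to microvolts.  A delimited file
    ``x.csv`` expects a sidecar ``x.json`` with keys ``sampling_rate`` and
    ``channel_labels``; rows are channels.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    if path.suffix.lower() in _DELIMITED:
        return _read_delimited(path)
    raise FormatError(f"unrecognized recording extension: {path.suffix!r}")


def _read_edf(path: Path) -> MultichannelRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate channel labels in EDF")
    return MultichannelRecording(data, float(raw.info["sfreq"]), labels)


def _read_delimited(path: Path) -> MultichannelRecording:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar.name} (sampling rate/labels)")
    meta = json.loads(sidecar.read_text())
    if "sampling_rate" not in meta:
        raise FormatError("sidecar missing 'sampling_rate'")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    data = np.loadtxt(path, delimiter=sep, ndmin=2)
    labels = meta.get("channel_labels") or [f"ch{i}" for i in range(data.shape[0])]
    return MultichannelRecording(data, float(meta["sampling_rate"]), list(labels))


def write_recording(rec: MultichannelRecording, path: str | Path) -> None:
    """Write a recording as EDF (16-bit) or delimited matrix + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        _write_edf(rec, path)
    elif path.suffix.lower() in _DELIMITED:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        np.savetxt(path, rec.data, delimiter=sep)
        path.with_suffix(".json").write_text(
            json.dumps(
                {"sampling_rate": rec.sampling_rate, "channel_labels": rec.channel_labels}
            )
        )
    else:
        raise FormatError(f"unrecognized recording extension: {path.suffix!r}")


def _write_edf(rec: MultichannelRecording, path: Path) -> None:
    """Minimal EDF writer: one data record per signal, 16-bit samples.

    Physical range is taken per channel from the data; values are quantized to
    the 16-bit digital range, which bounds the round-trip error at half a
    physical quantum.
    """
    n_ch, n_samp = rec.data.shape
    duration = n_samp / rec.sampling_rate

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise FormatError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    phys_min = np.minimum(rec.data.min(axis=1), -1.0)
    phys_max = np.maximum(rec.data.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad("1", 8),  # one data record
            pad(f"{duration:.6f}"[:8].rstrip("."), 8),
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        b"".join(pad(lbl, 16) for lbl in rec.channel_labels),
        b"".join(pad("", 80) for _ in range(n_ch)),  # transducer
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_min),
        b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_max),
        b"".join(pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),  # prefiltering
        b"".join(pad(str(n_samp), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),  # reserved
    ]
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    digital = np.round((rec.data - pmin[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        fh.write(digital.tobytes())  # record-major == channel-major for 1 record


# ---------------------------------------------------------------------------
# feature tables on disk
# ---------------------------------------------------------------------------

_LINEAGE_COLS = ["label", "participant", "trial", "segment"]


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame (features + lineage columns)."""
    if not vectors:
        raise FormatError("no feature vectors to tabulate")
    names = vectors[0].names
    for v in vectors:
        if v.names != names:
            raise FormatError("inconsistent feature names across vectors")
    mat = np.stack([v.values for v in vectors])
    df = pd.DataFrame(mat, columns=names)
    df["label"] = [v.label for v in vectors]
    df["participant"] = [v.lineage[0] for v in vectors]
    df["trial"] = [v.lineage[1] for v in vectors]
    df["segment"] = [v.lineage[2] for v in vectors]
    return df


def frame_to_features(df: pd.DataFrame) -> list[FeatureVector]:
    names = [c for c in df.columns if c not in _LINEAGE_COLS]
    missing = [c for c in _LINEAGE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureVector(
                values=row[names].to_numpy(dtype=float),
                names=names,
                label=int(row["label"]),
                lineage=(int(row["participant"]), int(row["trial"]), int(row["segment"])),
            )
        )
    return out


def write_features(vectors: list[FeatureVector], path: str | Path) -> None:
    """Write feature vectors as CSV, one row per segment."""
    features_to_frame(vectors).to_csv(path, index=False)


def read_features(path: str | Path) -> list[FeatureVector]:
    """Read a feature CSV written by :func:`write_features`."""
    # a ragged row raises on parse; a consistent-but-wrong width fails the
    # lineage-column check in frame_to_features
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed feature table: {exc}") from exc
    return frame_to_features(df)
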