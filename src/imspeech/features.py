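"""Six statistical features per channel per sub-band, vectorized.

Statistics are (mean, absolute mean, variance, standard deviation, skewness,
kurtosis).  Conventions: variance and standard deviation use the n-1
(sample) normalization with variance = std**2 exactly; skewness and kurtosis
are the biased standardized central moments, so a normal distribution has
kurtosis 3 (no excess subtraction).  Zero-variance inputs return skewness and
kurtosis of 0 rather than NaN, which also serves as the padding convention
when a decomposition yields fewer sub-bands than requested.

The vector ordering contract is channel-major, then sub-band, then statistic;
names are ``ch{c}_band{b}_{stat}``.  The fastest mode (IMF 1) is excluded by
default: features use IMFs 2-9.
"""

from __future__ import annotations

import logging

import numpy as np

from .emd import IMFSet
from .io import ConfigurationError, FeatureVector, Segment, STAT_NAMES

logger = logging.getLogger("imspeech")

DEFAULT_BANDS = (2, 3, 4, 5, 6, 7, 8, 9)

#: statistics of an all-zero (padded) sub-band under the conventions above
ZERO_SIGNAL_STATS = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def six_stats(x: np.ndarray) -> tuple[float, float, float, float, float, float]:
    """(mean, |mean|, variance, std, skewness, kurtosis) of a sequence."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ConfigurationError("need at least 2 samples for the six statistics")
    mean = float(np.mean(x))
    absmean = float(np.mean(np.abs(x)))
    std = float(np.std(x, ddof=1))
    var = std * std  # variance = std**2 exactly, by construction
    centered = x - mean
    m2 = float(np.mean(centered ** 2))
    if m2 == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(np.mean(centered ** 3) / m2 ** 1.5)
        kurt = float(np.mean(centered ** 4) / m2 ** 2)
    return (mean, absmean, var, std, skew, kurt)


def imf_features(imfset: IMFSet, use_bands: tuple[int, ...] = DEFAULT_BANDS,
                 label: int = -1,
                 lineage: tuple[int, int, int] = (-1, -1, -1)) -> FeatureVector:
    """Six statistics per channel per selected IMF (1-based band indices).

    Bands beyond the number of extracted IMFs are padded with the zero-signal
    statistics so the vector length is fixed at channels x bands x 6.
    """
    if imfset.n_imfs == 0:
        raise ConfigurationError("empty IMF set")
    values: list[float] = []
    names: list[str] = []
    padded = []
    for c in range(imfset.n_channels):
        for b in use_bands:
            if b < 1:
                raise ConfigurationError("band indices are 1-based")
            if b <= imfset.n_imfs:
                stats = six_stats(imfset.imfs[c, b - 1])
            else:
                stats = ZERO_SIGNAL_STATS
                padded.append((c, b))
            values.extend(stats)
            names.extend(f"ch{c}_band{b}_{s}" for s in STAT_NAMES)
    if padded:
        logger.info("padded %d missing (channel, band) sub-bands with zeros",
                    len(padded))
    return FeatureVector(values=np.array(values), names=names, label=label,
                         lineage=lineage)


def segment_features(segment: Segment, imfset: IMFSet,
                     use_bands: tuple[int, ...] = DEFAULT_BANDS) -> FeatureVector:
    """IMF features of a segment's decomposition, carrying its lineage."""
    return imf_features(
        imfset, use_bands=use_bands, label=segment.label,
        lineage=(segment.participant, segment.trial_id, segment.segment_index),
    )


class Standardizer:
    """Per-column z-scoring fitted on training data only.

    Columns with zero training standard deviation are centered but not
    scaled.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, train: np.ndarray) -> "Standardizer":
        train = np.asarray(train, dtype=float)
        if train.size == 0:
            raise ConfigurationError("empty training matrix")
        self.mean_ = train.mean(axis=0)
        sd = train.std(axis=0, ddof=1) if train.shape[0] > 1 else np.zeros(train.shape[1])
        sd = np.where(sd == 0, 1.0, sd)
        self.scale_ = sd
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.scale_ + self.mean_


def standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray, Standardizer]:
    """Z-score train and test using the training statistics only."""
    scaler = Standardizer().fit(train)
    return scaler.transform(train), scaler.transform(test), scaler
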