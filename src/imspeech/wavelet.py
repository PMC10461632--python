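"""Wavelet packet decomposition comparator.

A 3-level wavelet packet decomposition with the Daubechies-2 wavelet yields
eight terminal sub-bands, matching the eight IMF sub-bands the NA-MEMD route
uses.  Terminal nodes are frequency-ordered (not Paley/natural order) so that
node index is monotone in band, and the six statistics are computed on the
decimated coefficient sequences themselves.  Boundaries use symmetric signal
extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .io import ConfigurationError, FeatureVector, Segment, STAT_NAMES


@dataclass
class WPDCoefficients:
    """Terminal-node coefficient sequences of one channel, frequency-ordered.

    ``paths`` are the wavelet-packet tree paths ('a'/'d' strings) matching
    ``nodes``, kept so the inverse transform can repopulate the tree.
    """

    nodes: list[np.ndarray]
    wavelet: str
    level: int
    channel: int = 0
    paths: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def wpd(x: np.ndarray, level: int = 3, wavelet: str = "db2",
        channel: int = 0) -> WPDCoefficients:
    """Full wavelet packet decomposition to ``2**level`` terminal nodes."""
    x = np.asarray(x, dtype=float).ravel()
    filt_len = pywt.Wavelet(wavelet).dec_len
    if x.size < filt_len * 2 ** level:
        raise ConfigurationError(
            f"signal of {x.size} samples too short for level-{level} WPD "
            f"with {wavelet} (needs >= {filt_len * 2 ** level})"
        )
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode="symmetric", maxlevel=level)
    level_nodes = wp.get_level(level, order="freq")
    nodes = [np.asarray(node.data, dtype=float) for node in level_nodes]
    return WPDCoefficients(nodes=nodes, wavelet=wavelet, level=level,
                           channel=channel, paths=[n.path for n in level_nodes])


def wpd_reconstruct(coeffs: WPDCoefficients, n_samples: int) -> np.ndarray:
    """Inverse transform from all terminal nodes (perfect reconstruction)."""
    wp = pywt.WaveletPacket(data=None, wavelet=coeffs.wavelet, mode="symmetric",
                            maxlevel=coeffs.level)
    for path, data in zip(coeffs.paths, coeffs.nodes):
        wp[path] = data
    return np.asarray(wp.reconstruct(update=False), dtype=float)[:n_samples]


def wpd_features(segment: Segment, level: int = 3, wavelet: str = "db2") -> FeatureVector:
    """Six statistics per channel per terminal node, channel-major ordering.

    Mirrors the IMF feature contract: names are ``ch{c}_band{b}_{stat}`` with
    b the frequency-ordered node index 0..2**level-1.
    """
    from .features import six_stats  # shared statistic conventions

    values: list[float] = []
    names: list[str] = []
    for c in range(segment.data.shape[0]):
        coeffs = wpd(segment.data[c], level=level, wavelet=wavelet, channel=c)
        for b, node in enumerate(coeffs.nodes):
            stats = six_stats(node)
            values.extend(stats)
            names.extend(f"ch{c}_band{b}_{s}" for s in STAT_NAMES)
    return FeatureVector(
        values=np.array(values),
        names=names,
        label=segment.label,
        lineage=(segment.participant, segment.trial_id, segment.segment_index),
    )
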