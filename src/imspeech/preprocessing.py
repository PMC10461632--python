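"""Filtering and epoching chain: resample, high-pass, notch, reject, segment.

The chain order is fixed: resample -> high-pass -> notch -> (amplitude
rejection) -> trial-level train/test split (in evaluation) -> windowed
segmentation.  High-pass and notch are zero-phase (forward-backward) order-4
Butterworth filters, so the effective magnitude order is 8; zero-phase
filtering is the common EEG convention and keeps feature timing undistorted.
Resampling is polyphase with the built-in anti-aliasing low-pass.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal

from .io import ConfigurationError, MultichannelRecording, Segment, Trial

logger = logging.getLogger("imspeech")


def resample(rec: MultichannelRecording, target_rate: float) -> MultichannelRecording:
    """Polyphase resampling to ``target_rate`` (anti-aliased when decimating)."""
    if target_rate <= 0:
        raise ConfigurationError("target_rate must be positive")
    if target_rate == rec.sampling_rate:
        return MultichannelRecording(
            rec.data.copy(), rec.sampling_rate, list(rec.channel_labels), rec.annotations
        )
    ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return MultichannelRecording(out, target_rate, list(rec.channel_labels))


def highpass(rec: MultichannelRecording, cutoff: float, order: int = 4) -> MultichannelRecording:
    """Zero-phase Butterworth high-pass; removes DC and drift below ``cutoff``.

    A corner as low as 0.1 Hz has a settling time (~1/cutoff) that typically
    exceeds an epoch, so the forward-backward pass uses Gustafsson initial
    conditions, which minimize edge transients instead of padding, and the
    residual channel means are subtracted exactly afterwards.  The effective
    magnitude response is the squared Butterworth (order doubles).
    """
    nyq = rec.sampling_rate / 2
    if not 0 < cutoff < nyq:
        raise ConfigurationError(f"cutoff must be in (0, {nyq}) Hz")
    b, a = signal.butter(order, cutoff, btype="highpass", fs=rec.sampling_rate)
    out = signal.filtfilt(b, a, rec.data, axis=1, method="gust")
    out = out - out.mean(axis=1, keepdims=True)
    return MultichannelRecording(out, rec.sampling_rate, list(rec.channel_labels))


def notch(rec: MultichannelRecording, band_low: float = 59.0, band_high: float = 61.0,
          order: int = 4) -> MultichannelRecording:
    """Zero-phase Butterworth band-stop for powerline interference."""
    nyq = rec.sampling_rate / 2
    if not 0 < band_low < band_high < nyq:
        raise ConfigurationError(
            f"need 0 < band_low < band_high < {nyq}, got ({band_low}, {band_high})"
        )
    sos = signal.butter(order, (band_low, band_high), btype="bandstop",
                        fs=rec.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return MultichannelRecording(out, rec.sampling_rate, list(rec.channel_labels))


def preprocess_recording(rec: MultichannelRecording, target_rate: float = 250.0,
                         hp_cutoff: float = 0.1,
                         notch_band: tuple[float, float] = (59.0, 61.0),
                         notch_order: int = 4) -> MultichannelRecording:
    """The full filtering chain in its fixed order."""
    out = resample(rec, target_rate)
    out = highpass(out, hp_cutoff)
    out = notch(out, notch_band[0], notch_band[1], notch_order)
    return out


def segment_trial(trial: Trial, window: float, step: float) -> list[Segment]:
    """Slice a trial into overlapping windows carrying the trial's lineage.

    Windows are half-open sample ranges ``[i*step_samples, ... + window_samples)``;
    a 3 s trial at 250 Hz with 1 s windows and 0.5 s step yields five segments.
    """
    rec = trial.recording
    w = round(window * rec.sampling_rate)
    s = round(step * rec.sampling_rate)
    if s <= 0:
        raise ConfigurationError("step must be positive")
    if w > rec.n_samples:
        raise ConfigurationError(
            f"window of {w} samples exceeds trial length {rec.n_samples}"
        )
    n_segments = (rec.n_samples - w) // s + 1
    segments = []
    for i in range(n_segments):
        start = i * s
        segments.append(
            Segment(
                data=rec.data[:, start:start + w].copy(),
                label=trial.label,
                lineage=(trial.participant, trial.session, trial.trial_id, i),
                sampling_rate=rec.sampling_rate,
            )
        )
    return segments


def reject_noisy_trials(trials: list[Trial], amplitude_threshold: float = 100.0) -> list[Trial]:
    """Drop trials containing any sample beyond ``amplitude_threshold`` (µV).

    An automatic stand-in for manual visual rejection: the protocol this
    emulates rejected noisy trials by eye, without published criteria.
    """
    if amplitude_threshold <= 0:
        raise ConfigurationError("amplitude_threshold must be positive")
    kept, dropped = [], []
    for t in trials:
        if np.any(np.abs(t.recording.data) > amplitude_threshold):
            dropped.append((t.participant, t.trial_id))
        else:
            kept.append(t)
    if dropped:
        logger.info("rejected %d noisy trials: %s", len(dropped), dropped)
    return kept
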