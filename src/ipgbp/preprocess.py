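"""Front-end emulation and beat extraction.

Digital stand-in for the analog front end: a 4th-order Butterworth band-pass
over 0.3–5 Hz (covering the 0.67–3.33 Hz heart-rate band and its first
harmonics), applied zero-phase so beat morphology is preserved for feature
extraction.  Segmentation detects systolic peaks and cuts trough-to-trough
beats; per trial, the k beats nearest the cuff operating time are selected
and resampled/min-max-normalized to a fixed length.

Note the sign convention: arterial impedance falls when pressure rises, so
the raw IPG waveform is inverted (``invert=True`` in the trial helpers) to
make systole a *peak* before segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ipgbp.synthetic import TrialRecord

__all__ = [
    "BeatSegment",
    "InsufficientBeatsError",
    "bandpass_filter",
    "segment_beats",
    "select_trial_beats",
    "normalize_beat",
    "extract_trial_beats",
]


@dataclass
class BeatSegment:
    """One segmented beat: anchor metadata plus (optionally) its samples."""

    subject_id: str
    trial_index: int
    beat_index: int
    samples: np.ndarray
    fs_original: float
    t_start: float
    t_anchor: float


class InsufficientBeatsError(RuntimeError):
    """Raised when a trial yields fewer segmentable beats than requested."""


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = 0.3,
    high: float = 5.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass; same length as input."""
    if not (0.0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= fs / 2.0:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {fs / 2.0} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def butterworth_gain(f: float, low: float = 0.3, high: float = 5.0, order: int = 4) -> float:
    """Analytic magnitude response of the band-pass at frequency ``f`` (single pass).

    Band-pass of order n maps from an order-n low-pass prototype via
    s -> (s^2 + w0^2) / (B s); |H| = 1 / sqrt(1 + W^2n) with
    W = (f^2 - f_low*f_high) / (f * (f_high - f_low)).
    """
    w = (f**2 - low * high) / (f * (high - low))
    return 1.0 / np.sqrt(1.0 + w ** (2 * order))


def segment_beats(
    x: np.ndarray,
    fs: float,
    min_hr: float = 0.67,
    max_hr: float = 3.33,
    prominence_rel: float = 0.3,
    subject_id: str = "",
    trial_index: int = 0,
) -> list[BeatSegment]:
    """Detect systolic peaks and cut trough-to-trough beats around each.

    Peaks must be at least ``fs / max_hr`` samples apart with prominence at
    least ``prominence_rel`` times the signal's peak-to-peak range.  Returns
    an empty list when nothing qualifies (flat or all-noise input).
    """
    x = np.asarray(x, dtype=float)
    ptp = float(np.ptp(x))
    if ptp <= 0 or not np.all(np.isfinite(x)):
        return []
    distance = max(int(fs / max_hr), 1)
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=prominence_rel * ptp)
    if peaks.size == 0:
        return []

    # beat boundaries: minimum between consecutive peaks; edges extend at
    # most half a slowest-beat period beyond the outer peaks
    half_max = int(fs / min_hr / 2)
    bounds = [max(int(peaks[0]) - half_max, 0)]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(a + np.argmin(x[a:b])))
    bounds.append(min(int(peaks[-1]) + half_max, x.size))

    beats = []
    for k, pk in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 1]
        beats.append(
            BeatSegment(
                subject_id=subject_id,
                trial_index=trial_index,
                beat_index=k + 1,
                samples=x[lo:hi].copy(),
                fs_original=fs,
                t_start=lo / fs,
                t_anchor=pk / fs,
            )
        )
    return beats


def select_trial_beats(beats: list[BeatSegment], cuff_time: float, k: int = 5) -> list[BeatSegment]:
    """The ``k`` beats whose anchors are nearest ``cuff_time``, in time order.

    Ties in distance resolve to the earlier beat.  Raises
    :class:`InsufficientBeatsError` when fewer than ``k`` beats exist.
    """
    if len(beats) < k:
        trial = beats[0].trial_index if beats else "?"
        raise InsufficientBeatsError(
            f"trial {trial}: {len(beats)} beats segmented, {k} required"
        )
    order = sorted(
        range(len(beats)),
        key=lambda i: (abs(beats[i].t_anchor - cuff_time), beats[i].t_anchor),
    )
    chosen = sorted(order[:k])
    out = []
    for new_idx, i in enumerate(chosen, start=1):
        b = beats[i]
        out.append(BeatSegment(b.subject_id, b.trial_index, new_idx, b.samples, b.fs_original, b.t_start, b.t_anchor))
    return out


def normalize_beat(samples: np.ndarray, target_len: int = 128) -> np.ndarray:
    """Resample to ``target_len`` (linear interpolation) and min-max scale to [0, 1].

    A constant beat maps to the zero vector (degenerate but defined).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("beat must be non-empty")
    if samples.size == 1:
        y = np.full(target_len, samples[0])
    else:
        xi = np.linspace(0.0, samples.size - 1, target_len)
        y = np.interp(xi, np.arange(samples.size), samples)
    rng = y.max() - y.min()
    if rng == 0:
        return np.zeros(target_len)
    return (y - y.min()) / rng


def extract_trial_beats(
    trial: TrialRecord,
    subject_id: str = "",
    k: int = 5,
    target_len: int = 128,
    invert: bool = True,
) -> list[BeatSegment]:
    """Full per-trial chain: band-pass → (invert) → segment → select k → normalize.

    ``invert`` flips the filtered impedance so systole is a peak (impedance
    anticorrelates with pressure).
    """
    filt = bandpass_filter(trial.signal, trial.fs)
    if invert:
        filt = -filt
    beats = segment_beats(filt, trial.fs, subject_id=subject_id, trial_index=trial.trial_index)
    chosen = select_trial_beats(beats, trial.cuff_time, k=k)
    for b in chosen:
        b.samples = normalize_beat(b.samples, target_len)
    return chosen
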