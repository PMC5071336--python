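"""Syllable detection and classification from ultrasonic audio.

The analysis chain is: short-time power spectrum ("sonogram") of the raw
waveform, robust per-frequency-row noise thresholding, band limiting to the
USV range, silence-gap segmentation into syllables, peak-frequency (pitch)
tracking, and classification of each syllable by the pitch jumps that
separate its notes:

* ``s`` — simple, no pitch jump;
* ``u`` — two notes separated by one upward jump;
* ``d`` — two notes separated by one downward jump;
* ``m`` — three or more notes (two or more jumps);
* ``unclassified`` — sounds too broadband or too fragmented to score,
  removed from all downstream analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "SonogramConfig",
    "Sonogram",
    "PitchTrack",
    "AcousticFeatures",
    "SyllableEvent",
    "compute_sonogram",
    "denoise_and_band_limit",
    "detect_syllables",
    "extract_pitch_track",
    "classify_syllable",
    "extract_features",
    "analyze_waveform",
    "read_wav",
    "events_to_table",
    "SYLLABLE_TABLE_COLUMNS",
]

#: Power-spectrum value produced by a full-scale (amplitude 1.0) sinusoid
#: under the one-sided 'spectrum' scaling used here; reference for dB.
_FULL_SCALE_POWER = 0.5


@dataclass(frozen=True)
class SonogramConfig:
    """Parameters of the sonogram / syllable-detection stage.

    Defaults follow the standard mouse-song settings: 256-sample blocks with
    half overlap, a 35–125 kHz analysis band, a 10 ms minimum silence
    between syllables and a 3 ms minimum syllable duration.
    """

    block_size: int = 256
    overlap_fraction: float = 0.5
    band_low_khz: float = 35.0
    band_high_khz: float = 125.0
    noise_threshold_method: str = "median_mad"  # or "none"
    noise_mad_factor: float = 15.0
    min_silence_ms: float = 10.0
    min_syllable_ms: float = 3.0
    pitch_jump_min_khz: float = 10.0
    window: str = "boxcar"
    edge_trim_fraction: float = 0.1
    max_missing_bridge: int = 3
    min_defined_fraction: float = 0.5
    min_spectral_purity: float = 0.1

    def __post_init__(self) -> None:
        if self.block_size <= 0:
            raise ValueError("block_size must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.band_low_khz >= self.band_high_khz:
            raise ValueError("band_low_khz must be below band_high_khz")
        if self.noise_threshold_method not in ("median_mad", "none"):
            raise ValueError(
                f"unknown noise_threshold_method {self.noise_threshold_method!r}"
            )

    def hop(self) -> int:
        """Samples advanced between consecutive blocks."""
        hop = int(round(self.block_size * (1.0 - self.overlap_fraction)))
        return max(hop, 1)


@dataclass
class Sonogram:
    """Short-time power spectrum: frequency bins x time frames.

    ``power`` may be a thresholded (masked) matrix; in that case
    ``raw_power`` retains the unmasked band-limited values (used for
    spectral purity, which is defined on the pre-threshold spectrum) and
    ``noise_threshold`` records the per-row threshold applied.
    """

    power: np.ndarray
    freqs_khz: np.ndarray
    times_s: np.ndarray
    frame_step_s: float
    raw_power: np.ndarray | None = None
    noise_threshold: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("sonogram power must be nonnegative")
        if self.freqs_khz.size > 1 and not np.all(np.diff(self.freqs_khz) > 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.power.shape[1]

    def frame_slice(self, onset_s: float, offset_s: float) -> slice:
        """Frames whose centers fall in the half-open interval [onset, offset)."""
        i0 = int(np.searchsorted(self.times_s, onset_s - 1e-12))
        i1 = int(np.searchsorted(self.times_s, offset_s - 1e-12))
        return slice(i0, i1)


@dataclass
class PitchTrack:
    """Per-frame peak frequency and power over one syllable.

    ``freq_khz`` is NaN at frames where no power survived thresholding.
    ``peak_power`` / ``total_power`` are taken from the unmasked band-limited
    spectrum so that spectral purity reflects the true energy distribution.
    """

    freq_khz: np.ndarray
    peak_power: np.ndarray
    total_power: np.ndarray
    start_frame: int = 0

    @property
    def n_frames(self) -> int:
        return self.freq_khz.size

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.freq_khz)


@dataclass(frozen=True)
class AcousticFeatures:
    duration_ms: float
    mean_freq_khz: float
    min_freq_khz: float
    max_freq_khz: float
    start_freq_khz: float
    end_freq_khz: float
    freq_modulation_khz: float
    spectral_purity: float
    amplitude_db: float
    bandwidth_khz: float

    def __post_init__(self) -> None:
        if not (self.min_freq_khz - 1e-9 <= self.mean_freq_khz <= self.max_freq_khz + 1e-9):
            raise ValueError("mean frequency outside [min, max]")
        if not -1e-9 <= self.spectral_purity <= 1 + 1e-9:
            raise ValueError("spectral purity outside [0, 1]")


@dataclass
class SyllableEvent:
    label: str
    onset_s: float
    offset_s: float
    pitch_track: PitchTrack
    features: AcousticFeatures | None
    n_pitch_jumps: int
    jump_directions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must exceed onset")


def read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    """Read a mono PCM-16 or float WAV; return (rate, float waveform in [-1, 1])."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(np.float64) / 2147483648.0
    else:
        data = np.asarray(data, dtype=np.float64)
    return int(rate), data


def compute_sonogram(
    waveform: np.ndarray, rate: float, config: SonogramConfig | None = None
) -> Sonogram:
    """Short-time power spectrum over the full Nyquist range.

    Block size and overlap come from ``config`` (defaults 256 samples, half
    overlap). With ``rate`` = 250 kHz the bin width is 976.5625 Hz and the
    frame step 0.512 ms.
    """
    config = config or SonogramConfig()
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.size == 0:
        raise ValueError("empty waveform")
    min_rate = 2.0 * config.band_high_khz * 1000.0
    if rate < min_rate:
        raise ValueError(
            f"sampling rate {rate:g} Hz too low for a {config.band_high_khz:g} kHz "
            f"band; need at least {min_rate:g} Hz"
        )
    if waveform.size < config.block_size:
        raise ValueError(
            f"waveform shorter ({waveform.size}) than one block ({config.block_size})"
        )
    hop = config.hop()
    noverlap = config.block_size - hop
    freqs, times, power = signal.spectrogram(
        waveform,
        fs=rate,
        window=signal.get_window(config.window, config.block_size),
        nperseg=config.block_size,
        noverlap=noverlap,
        detrend=False,
        scaling="spectrum",
        mode="psd",
    )
    return Sonogram(
        power=power,
        freqs_khz=freqs / 1000.0,
        times_s=times,
        frame_step_s=hop / rate,
    )


def _noise_threshold(power: np.ndarray, k: float) -> float:
    """Global in-band noise floor: cell median + k * MAD.

    Pooling all in-band cells keeps the estimate dominated by noise even
    when a long syllable occupies most frames of its frequency rows, which
    would corrupt a rowwise estimate."""
    med = float(np.median(power))
    mad = float(np.median(np.abs(power - med)))
    return med + k * mad


def denoise_and_band_limit(sonogram: Sonogram, config: SonogramConfig | None = None) -> Sonogram:
    """Truncate to the analysis band and zero cells below the noise floor.

    The noise floor is the median + k * MAD (k = ``noise_mad_factor``) of
    all in-band cells, so it stays noise-dominated as long as syllables
    cover a minority of the time-frequency plane. The unmasked band-limited
    power and the threshold used are kept on the returned object.
    """
    config = config or SonogramConfig()
    in_band = (sonogram.freqs_khz >= config.band_low_khz) & (
        sonogram.freqs_khz <= config.band_high_khz
    )
    if not np.any(in_band):
        raise ValueError(
            f"band {config.band_low_khz}-{config.band_high_khz} kHz outside "
            f"sonogram range {sonogram.freqs_khz[0]:.1f}-{sonogram.freqs_khz[-1]:.1f} kHz"
        )
    raw = sonogram.power[in_band]
    if config.noise_threshold_method == "median_mad":
        thr = np.full(raw.shape[0], _noise_threshold(raw, config.noise_mad_factor))
    else:
        thr = np.zeros(raw.shape[0])
    masked = np.where(raw < thr[:, None], 0.0, raw)
    return Sonogram(
        power=masked,
        freqs_khz=sonogram.freqs_khz[in_band],
        times_s=sonogram.times_s,
        frame_step_s=sonogram.frame_step_s,
        raw_power=raw,
        noise_threshold=thr,
    )


def detect_syllables(
    masked: Sonogram, config: SonogramConfig | None = None
) -> list[tuple[float, float]]:
    """Segment voiced frames into syllables.

    A frame is voiced if any in-band cell survived thresholding. Voiced runs
    separated by silent gaps shorter than ``min_silence_ms`` are merged
    (gaps of exactly the minimum separate); merged runs shorter than
    ``min_syllable_ms`` are discarded. Because an analysis block straddles
    its frame center, edge frames that barely overlap a sound are voiced
    too; run edges whose frame power falls below ``edge_trim_fraction`` of
    the run's median frame power are trimmed so boundaries land within one
    frame step of the physical sound. Returned intervals are half-open
    ``[onset, offset)`` in seconds, non-overlapping and sorted.
    """
    config = config or SonogramConfig()
    if masked.n_frames == 0:
        return []
    frame_power = masked.power.sum(axis=0)
    voiced = frame_power > 0
    if not voiced.any():
        return []
    step = masked.frame_step_s
    edges = np.diff(voiced.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if voiced[0]:
        starts.insert(0, 0)
    if voiced[-1]:
        ends.append(voiced.size)
    runs: list[list[int]] = []
    for s, e in zip(starts, ends):
        if runs and (s - runs[-1][1]) * step * 1000.0 < config.min_silence_ms:
            runs[-1][1] = e
        else:
            runs.append([s, e])
    out: list[tuple[float, float]] = []
    for s, e in runs:
        floor = config.edge_trim_fraction * float(np.median(frame_power[s:e]))
        while s < e and frame_power[s] < floor:
            s += 1
        while e > s and frame_power[e - 1] < floor:
            e -= 1
        if (e - s) * step * 1000.0 >= config.min_syllable_ms:
            onset = masked.times_s[s] - step / 2.0
            offset = masked.times_s[e - 1] + step / 2.0
            out.append((onset, offset))
    return out


def extract_pitch_track(sonogram: Sonogram, interval: tuple[float, float]) -> PitchTrack:
    """Peak-frequency track over ``interval``.

    Peak frequency per frame is the in-band bin with maximal surviving
    power; frames with no surviving power are marked missing (NaN). Peak and
    total power are read from the unmasked spectrum when available.
    """
    sl = sonogram.frame_slice(*interval)
    if sl.stop <= sl.start:
        raise ValueError(f"interval {interval} covers no frames")
    masked = sonogram.power[:, sl]
    raw = masked if sonogram.raw_power is None else sonogram.raw_power[:, sl]
    peak_bin = np.argmax(masked, axis=0)
    frame_idx = np.arange(masked.shape[1])
    has_power = masked[peak_bin, frame_idx] > 0
    freq = np.where(has_power, sonogram.freqs_khz[peak_bin], np.nan)
    return PitchTrack(
        freq_khz=freq,
        peak_power=raw[peak_bin, frame_idx],
        total_power=raw.sum(axis=0),
        start_frame=sl.start,
    )


def classify_syllable(
    track: PitchTrack, config: SonogramConfig | None = None
) -> tuple[str, list[str]]:
    """Label a syllable by its pitch jumps.

    A jump is a frequency change of at least ``pitch_jump_min_khz`` between
    consecutive defined frames; runs of up to ``max_missing_bridge`` missing
    frames are bridged (the change is measured across the gap), longer
    missing runs split the track into notes with no jump scored across them.
    """
    config = config or SonogramConfig()
    defined = np.flatnonzero(track.defined)
    if defined.size == 0:
        return "unclassified", []
    freqs = track.freq_khz[defined]
    jumps: list[str] = []
    for j in range(defined.size - 1):
        gap = defined[j + 1] - defined[j] - 1
        if gap > config.max_missing_bridge:
            continue
        df = freqs[j + 1] - freqs[j]
        if df >= config.pitch_jump_min_khz:
            jumps.append("up")
        elif -df >= config.pitch_jump_min_khz:
            jumps.append("down")
    n = len(jumps)
    if n == 0:
        label = "s"
    elif n == 1:
        label = "u" if jumps[0] == "up" else "d"
    else:
        label = "m"
    return label, jumps


def extract_features(
    sonogram: Sonogram,
    track: PitchTrack,
    interval: tuple[float, float],
) -> AcousticFeatures:
    """Spectral features of one syllable.

    Spectral purity is the per-frame peak power divided by the total in-band
    power, averaged over defined frames: 1 for a pure tone, near 0 for white
    noise. Amplitude is the mean in-band power in dB relative to full scale.
    Frequency modulation and bandwidth are both the span (max - min) of the
    pitch track.
    """
    defined = track.defined
    if not defined.any():
        raise ValueError("no defined frames in pitch track")
    freqs = track.freq_khz[defined]
    tot = track.total_power[defined]
    purity = float(np.mean(track.peak_power[defined] / np.where(tot > 0, tot, np.inf)))
    mean_power = float(np.mean(track.total_power))
    amplitude_db = 10.0 * math.log10(max(mean_power, 1e-300) / _FULL_SCALE_POWER)
    fmin, fmax = float(freqs.min()), float(freqs.max())
    onset, offset = interval
    return AcousticFeatures(
        duration_ms=(offset - onset) * 1000.0,
        mean_freq_khz=float(freqs.mean()),
        min_freq_khz=fmin,
        max_freq_khz=fmax,
        start_freq_khz=float(freqs[0]),
        end_freq_khz=float(freqs[-1]),
        freq_modulation_khz=fmax - fmin,
        spectral_purity=min(purity, 1.0),
        amplitude_db=amplitude_db,
        bandwidth_khz=fmax - fmin,
    )


def analyze_waveform(
    waveform: np.ndarray, rate: float, config: SonogramConfig | None = None
) -> list[SyllableEvent]:
    """Full acoustic stage: waveform in, classified syllable events out.

    Syllables whose defined-frame fraction falls below
    ``min_defined_fraction`` or whose spectral purity falls below
    ``min_spectral_purity`` (broadband mechanical noise) are labeled
    ``unclassified``; downstream sequence analyses drop them.
    """
    config = config or SonogramConfig()
    son = compute_sonogram(waveform, rate, config)
    masked = denoise_and_band_limit(son, config)
    events: list[SyllableEvent] = []
    for onset, offset in detect_syllables(masked, config):
        track = extract_pitch_track(masked, (onset, offset))
        label, jumps = classify_syllable(track, config)
        feats: AcousticFeatures | None = None
        if track.defined.any():
            feats = extract_features(masked, track, (onset, offset))
            frac = track.defined.mean()
            if frac < config.min_defined_fraction or (
                feats.spectral_purity < config.min_spectral_purity
            ):
                label = "unclassified"
        events.append(
            SyllableEvent(
                label=label,
                onset_s=onset,
                offset_s=offset,
                pitch_track=track,
                features=feats,
                n_pitch_jumps=len(jumps),
                jump_directions=jumps,
            )
        )
    return events


SYLLABLE_TABLE_COLUMNS = [
    "file",
    "onset_s",
    "offset_s",
    "label",
    "duration_ms",
    "mean_freq_khz",
    "min_freq_khz",
    "max_freq_khz",
    "start_freq_khz",
    "end_freq_khz",
    "freq_modulation_khz",
    "spectral_purity",
    "amplitude_db",
    "bandwidth_khz",
    "n_pitch_jumps",
]


def events_to_table(events: Sequence[SyllableEvent], file: str = "") -> pd.DataFrame:
    """Flatten syllable events into the standard syllable CSV schema."""
    rows = []
    for ev in events:
        f = ev.features
        rows.append(
            {
                "file": file,
                "onset_s": ev.onset_s,
                "offset_s": ev.offset_s,
                "label": ev.label,
                "duration_ms": f.duration_ms if f else np.nan,
                "mean_freq_khz": f.mean_freq_khz if f else np.nan,
                "min_freq_khz": f.min_freq_khz if f else np.nan,
                "max_freq_khz": f.max_freq_khz if f else np.nan,
                "start_freq_khz": f.start_freq_khz if f else np.nan,
                "end_freq_khz": f.end_freq_khz if f else np.nan,
                "freq_modulation_khz": f.freq_modulation_khz if f else np.nan,
                "spectral_purity": f.spectral_purity if f else np.nan,
                "amplitude_db": f.amplitude_db if f else np.nan,
                "bandwidth_khz": f.bandwidth_khz if f else np.nan,
                "n_pitch_jumps": ev.n_pitch_jumps,
            }
        )
    return pd.DataFrame(rows, columns=SYLLABLE_TABLE_COLUMNS)
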