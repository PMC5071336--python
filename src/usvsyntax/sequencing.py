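"""Song-bout segmentation and sequence-level summary statistics.

A sequence (song bout) is a run of classified syllables whose
inter-syllable intervals (ISIs) all fall below a break threshold; a silence
of 250 ms or more ends the bout. Unclassified syllables are removed before
gap computation, so a removed event's span counts toward the gap it leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SyllableSequence",
    "SessionSummary",
    "SYLLABLE_LABELS",
    "compute_isi_distribution",
    "segment_into_sequences",
    "letter_code",
    "parse_letter_code",
    "complex_simple_ratio",
    "session_summary",
    "rate_length_correlation",
    "sequences_to_table",
]

SYLLABLE_LABELS = ("s", "d", "u", "m")

#: Silence of at least this many milliseconds separates two song bouts.
DEFAULT_BREAK_MS = 250.0


@dataclass
class SyllableSequence:
    """One song bout: ordered syllables with timing, owned by one animal."""

    labels: list[str]
    onsets_s: np.ndarray
    offsets_s: np.ndarray
    animal_id: str = ""
    context: str = ""
    bout_index: int = 0

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("a sequence holds at least one syllable")
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.offsets_s = np.asarray(self.offsets_s, dtype=float)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def start_s(self) -> float:
        return float(self.onsets_s[0])

    @property
    def end_s(self) -> float:
        return float(self.offsets_s[-1])


@dataclass(frozen=True)
class SessionSummary:
    animal_id: str
    context: str
    session_minutes: float
    total_syllables: int
    syllable_rate_per_min: float
    repertoire: dict[str, float]  # proportions over {s,d,u,m}; NaN if empty
    n_sequences: int
    mean_sequence_length: float
    complex_simple_ratio: float


def compute_isi_distribution(
    onsets_s: np.ndarray,
    offsets_s: np.ndarray,
    n_bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inter-syllable intervals and a log-spaced histogram.

    Gaps are onset(i+1) - offset(i) for consecutive events. Returns
    ``(gaps_s, counts, bin_edges_s)``; with fewer than two events the gap
    list is empty and the histogram arrays are empty too.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    offsets = np.asarray(offsets_s, dtype=float)
    if onsets.size < 2:
        return np.array([]), np.array([]), np.array([])
    gaps = onsets[1:] - offsets[:-1]
    positive = gaps[gaps > 0]
    if positive.size == 0:
        return gaps, np.array([]), np.array([])
    edges = np.logspace(
        np.log10(positive.min()), np.log10(positive.max()), n_bins + 1
    )
    counts, edges = np.histogram(positive, bins=edges)
    return gaps, counts, edges


def segment_into_sequences(
    labels: Sequence[str],
    onsets_s: np.ndarray,
    offsets_s: np.ndarray,
    break_ms: float = DEFAULT_BREAK_MS,
    animal_id: str = "",
    context: str = "",
) -> list[SyllableSequence]:
    """Split events into song bouts at silences of ``break_ms`` or more.

    A gap exactly equal to the threshold splits. Every event belongs to
    exactly one bout and concatenating the bouts restores the event list.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    offsets = np.asarray(offsets_s, dtype=float)
    n = len(labels)
    if n == 0:
        return []
    if onsets.size != n or offsets.size != n:
        raise ValueError("labels, onsets and offsets must have equal length")
    gaps_ms = (onsets[1:] - offsets[:-1]) * 1000.0
    breaks = np.flatnonzero(gaps_ms >= break_ms) + 1
    bounds = [0, *breaks.tolist(), n]
    sequences = []
    for k, (i, j) in enumerate(zip(bounds[:-1], bounds[1:])):
        sequences.append(
            SyllableSequence(
                labels=list(labels[i:j]),
                onsets_s=onsets[i:j],
                offsets_s=offsets[i:j],
                animal_id=animal_id,
                context=context,
                bout_index=k,
            )
        )
    return sequences


def letter_code(sequences: Iterable[SyllableSequence | Sequence[str]]) -> list[str]:
    """One coded string per bout, e.g. ``[s, s, d, m]`` -> ``"ssdm"``."""
    coded = []
    for seq in sequences:
        labels = seq.labels if isinstance(seq, SyllableSequence) else list(seq)
        for lab in labels:
            if lab not in SYLLABLE_LABELS:
                raise ValueError(f"unknown syllable label {lab!r}")
        coded.append("".join(labels))
    return coded


def parse_letter_code(coded: Iterable[str]) -> list[list[str]]:
    """Inverse of :func:`letter_code`."""
    out = []
    for s in coded:
        labels = list(s)
        for lab in labels:
            if lab not in SYLLABLE_LABELS:
                raise ValueError(f"unknown syllable label {lab!r}")
        out.append(labels)
    return out


def complex_simple_ratio(
    sequences: Iterable[SyllableSequence | Sequence[str] | str],
) -> float:
    """Complex-to-simple song ratio.

    Among bouts of three or more syllables, the number containing at least
    two ``m`` syllables divided by the number containing one or none. Bouts
    of two syllables or less are excluded from both counts. Returns NaN
    when the denominator is zero.
    """
    n_complex = 0
    n_simple = 0
    for seq in sequences:
        labels = seq.labels if isinstance(seq, SyllableSequence) else list(seq)
        if len(labels) < 3:
            continue
        if labels.count("m") >= 2:
            n_complex += 1
        else:
            n_simple += 1
    if n_simple == 0:
        return float("nan")
    return n_complex / n_simple


def session_summary(
    labels: Sequence[str],
    sequences: Sequence[SyllableSequence],
    session_minutes: float,
    animal_id: str = "",
    context: str = "",
) -> SessionSummary:
    """Per-session rates, repertoire composition and bout lengths.

    Rate is classified syllables per minute; repertoire proportions are over
    the four classified categories and sum to 1 whenever at least one
    syllable was produced (all-NaN otherwise).
    """
    if session_minutes <= 0:
        raise ValueError("session_minutes must be positive")
    total = len(labels)
    if total:
        repertoire = {lab: labels.count(lab) / total for lab in SYLLABLE_LABELS}
    else:
        repertoire = {lab: float("nan") for lab in SYLLABLE_LABELS}
    n_seq = len(sequences)
    mean_len = (
        sum(len(s) for s in sequences) / n_seq if n_seq else float("nan")
    )
    return SessionSummary(
        animal_id=animal_id,
        context=context,
        session_minutes=session_minutes,
        total_syllables=total,
        syllable_rate_per_min=total / session_minutes,
        repertoire=repertoire,
        n_sequences=n_seq,
        mean_sequence_length=mean_len,
        complex_simple_ratio=complex_simple_ratio(sequences),
    )


def rate_length_correlation(
    mean_lengths: Sequence[float], rates: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of per-animal bout length vs syllable rate."""
    x = np.asarray(mean_lengths, dtype=float)
    y = np.asarray(rates, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 animals with defined rate and length")
    res = stats.spearmanr(x[ok], y[ok])
    return float(res.statistic), float(res.pvalue)


def sequences_to_table(sequences: Sequence[SyllableSequence]) -> pd.DataFrame:
    """Sequences CSV schema: one row per bout with its coded string."""
    rows = [
        {
            "animal_id": s.animal_id,
            "context": s.context,
            "bout_index": s.bout_index,
            "coded_string": "".join(s.labels),
            "n_syllables": len(s),
            "start_s": s.start_s,
            "end_s": s.end_s,
        }
        for s in sequences
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "context",
            "bout_index",
            "coded_string",
            "n_syllables",
            "start_s",
            "end_s",
        ],
    )
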