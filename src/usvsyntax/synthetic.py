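"""Synthetic corpora and audio with known ground truth.

Two generators stand in for recordings of a two-genotype, multi-context
study design:

* :func:`sample_cohort` — symbolic song corpora. Each animal-context gets a
  transition matrix drawn rowwise from a Dirichlet centered on an
  effect-modified group matrix, and song bouts are emitted by a Markov walk
  from silence until return to silence. Planted group effects are an
  additive shift of probability mass toward silence (shorter bouts) and a
  multiplicative suppression of transitions involving the complex ``m``
  syllable (reduced complex sequencing).
* :func:`synth_waveform` — waveforms of frequency-plateau syllables with
  programmed pitch jumps, raised-cosine ramps, inter-syllable gaps and
  additive white noise at a stated SNR, returned with an exact truth table.

The default baseline matrix is loosely shaped on the qualitative topology
of real mouse song (s-dominant bout starts; s, d and m self-loops; no u
self-loop) but its values are invented; it is a synthetic stand-in, not
measured data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from usvsyntax.syntax_stats import SILENCE, STATES

__all__ = [
    "CohortSpec",
    "Cohort",
    "default_baseline_matrix",
    "apply_silence_shift",
    "apply_m_suppression",
    "sample_cohort",
    "synth_waveform",
    "random_syllable_plans",
]

_X = STATES.index(SILENCE)
_LETTERS = np.array(list(STATES))


def default_baseline_matrix() -> np.ndarray:
    """Synthetic baseline transition matrix (rows: s, d, u, m, X).

    Invented values on a realistic topology; every row sums to 1 and the
    silence->silence cell is structurally zero.
    """
    return np.array(
        [
            #  s     d     u     m     X
            [0.45, 0.15, 0.05, 0.05, 0.30],  # from s
            [0.20, 0.30, 0.05, 0.10, 0.35],  # from d
            [0.30, 0.15, 0.00, 0.10, 0.45],  # from u
            [0.15, 0.10, 0.05, 0.30, 0.40],  # from m
            [0.75, 0.10, 0.10, 0.05, 0.00],  # from X (bout start)
        ]
    )


def _check_stochastic(p: np.ndarray) -> None:
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("every transition-matrix row must sum to 1")
    if p[_X, _X] != 0:
        raise ValueError("silence->silence must be structurally zero")


def apply_silence_shift(p: np.ndarray, delta: float) -> np.ndarray:
    """Shift ``delta`` of absolute probability mass toward silence.

    Applied to each syllable row (not the silence row); the remaining
    non-silence mass is rescaled proportionally so the row stays
    stochastic. Raises if any row would leave [0, 1].
    """
    out = np.array(p, dtype=float)
    for i in range(5):
        if i == _X:
            continue
        old_x = out[i, _X]
        new_x = old_x + delta
        if not -1e-12 <= new_x <= 1 + 1e-12:
            raise ValueError(
                f"silence shift {delta:+g} pushes row {STATES[i]!r} "
                f"silence probability to {new_x:g}, outside [0, 1]"
            )
        rest_old = 1.0 - old_x
        if rest_old <= 0 and delta != 0:
            raise ValueError(f"row {STATES[i]!r} has no non-silence mass to shift")
        scale = (1.0 - new_x) / rest_old if rest_old > 0 else 0.0
        out[i] = out[i] * scale
        out[i, _X] = np.clip(new_x, 0.0, 1.0)
    _check_stochastic(out)
    return out


def apply_m_suppression(p: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicatively suppress transitions involving the ``m`` syllable.

    Entries into ``m`` from any other state, and exits from ``m`` to
    anything but silence, are multiplied by ``factor``; the removed mass is
    redistributed proportionally over the row's unsuppressed cells (for the
    ``m`` row that pushes mass to m->silence, shortening complex bouts).
    """
    if factor < 0:
        raise ValueError("suppression factor must be nonnegative")
    m = STATES.index("m")
    out = np.array(p, dtype=float)
    for i in range(5):
        if i == m:
            suppressed = np.array([j != _X for j in range(5)])
        else:
            suppressed = np.zeros(5, dtype=bool)
            suppressed[m] = True
        keep = ~suppressed
        if i == _X:
            keep[_X] = False
        removed = out[i, suppressed].sum() * (1.0 - factor)
        out[i, suppressed] *= factor
        kept_mass = out[i, keep].sum()
        if removed > 0:
            if kept_mass <= 0:
                raise ValueError(
                    f"row {STATES[i]!r} has no unsuppressed mass to absorb the shift"
                )
            out[i, keep] *= 1.0 + removed / kept_mass
    _check_stochastic(out)
    return out


@dataclass
class CohortSpec:
    """Generative parameters of a two-group synthetic cohort.

    Defaults mirror the study design scale: 8 + 10 animals, 200 song bouts
    per animal-context, moderate between-animal dispersion (Dirichlet
    concentration 50, i.e. per-animal rows scatter around the group row
    with sd ~ sqrt(p(1-p)/51)). Effects are keyed by (group index,
    context).
    """

    n_animals: tuple[int, int] = (8, 10)
    contexts: tuple[str, ...] = ("UF",)
    baseline: np.ndarray | None = None
    concentration: float = 50.0
    n_sequences: int = 200
    max_syllables: int = 200
    silence_shift: Mapping[tuple[int, str], float] = field(default_factory=dict)
    m_suppression: Mapping[tuple[int, str], float] = field(default_factory=dict)

    def group_matrix(self, group: int, context: str) -> np.ndarray:
        """Effect-modified group-level transition matrix (validated)."""
        p = self.baseline if self.baseline is not None else default_baseline_matrix()
        _check_stochastic(np.asarray(p, dtype=float))
        p = apply_silence_shift(p, self.silence_shift.get((group, context), 0.0))
        p = apply_m_suppression(p, self.m_suppression.get((group, context), 1.0))
        return p


@dataclass
class Cohort:
    """Sampled corpora plus the per-animal ground-truth matrices."""

    corpora: dict[tuple[int, str, str], list[str]]  # (group, animal, context)
    truth: dict[tuple[int, str, str], np.ndarray]
    spec: CohortSpec
    seed: int

    def animals(self, group: int) -> list[str]:
        return sorted({a for g, a, _ in self.corpora if g == group})

    def corpus(self, group: int, animal: str, context: str) -> list[str]:
        return self.corpora[(group, animal, context)]

    def to_sequences_table(self) -> pd.DataFrame:
        rows = []
        for (g, animal, ctx), seqs in sorted(self.corpora.items()):
            for k, s in enumerate(seqs):
                rows.append(
                    {
                        "animal_id": animal,
                        "group": f"group{g + 1}",
                        "context": ctx,
                        "bout_index": k,
                        "coded_string": s,
                        "n_syllables": len(s),
                    }
                )
        return pd.DataFrame(rows)


def _animal_matrix(
    group_p: np.ndarray, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one animal's matrix rowwise from a Dirichlet around the group row.

    Cells the group never produces stay zero; infinite concentration
    returns the group matrix exactly."""
    if np.isinf(concentration):
        return group_p.copy()
    out = np.zeros_like(group_p)
    for i in range(5):
        support = group_p[i] > 0
        if not support.any():
            continue
        out[i, support] = rng.dirichlet(concentration * group_p[i, support])
    return out


def _sample_sequences(
    p: np.ndarray, n_seq: int, cap: int, rng: np.random.Generator
) -> list[str]:
    """Markov walks from silence until absorption back at silence."""
    cum = np.cumsum(p, axis=1)
    cum[:, -1] = np.maximum(cum[:, -1], 1.0)  # guard float rounding
    seq = np.full((n_seq, cap), -1, dtype=np.int8)
    cur = np.full(n_seq, _X, dtype=np.int64)
    alive = np.ones(n_seq, dtype=bool)
    lengths = np.zeros(n_seq, dtype=np.int64)
    for step in range(cap):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        u = rng.random(idx.size)
        nxt = (cum[cur[idx]] < u[:, None]).sum(axis=1)
        ended = nxt == _X
        rec = idx[~ended]
        seq[rec, step] = nxt[~ended]
        lengths[rec] += 1
        cur[idx] = nxt
        alive[idx[ended]] = False
    if alive.any():
        warnings.warn(
            f"{int(alive.sum())} walks truncated at the {cap}-syllable cap",
            stacklevel=2,
        )
    return ["".join(_LETTERS[seq[i, : lengths[i]]]) for i in range(n_seq)]


def sample_cohort(spec: CohortSpec, seed: int = 0) -> Cohort:
    """Generate a full two-group cohort; a pure function of (spec, seed)."""
    rng = np.random.default_rng(seed)
    corpora: dict[tuple[int, str, str], list[str]] = {}
    truth: dict[tuple[int, str, str], np.ndarray] = {}
    group_mats = {
        (g, c): spec.group_matrix(g, c)
        for g in range(len(spec.n_animals))
        for c in spec.contexts
    }
    for g, n in enumerate(spec.n_animals):
        for a in range(n):
            animal = f"g{g + 1}a{a + 1:02d}"
            for c in spec.contexts:
                p = _animal_matrix(group_mats[(g, c)], spec.concentration, rng)
                corpora[(g, animal, c)] = _sample_sequences(
                    p, spec.n_sequences, spec.max_syllables, rng
                )
                truth[(g, animal, c)] = p
    return Cohort(corpora=corpora, truth=truth, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# Audio synthesis


def _label_from_plan(plan: Sequence[tuple[float, float]], jump_min_khz: float) -> str:
    jumps = 0
    ups = 0
    for (f1, _), (f2, _) in zip(plan[:-1], plan[1:]):
        df = f2 - f1
        if abs(df) >= jump_min_khz:
            jumps += 1
            ups += df > 0
    if jumps == 0:
        return "s"
    if jumps == 1:
        return "u" if ups else "d"
    return "m"


def synth_waveform(
    plans: Sequence[Sequence[tuple[float, float]]],
    *,
    gaps_ms: float | Sequence[float] = 50.0,
    rate: float = 250_000.0,
    snr_db: float | None = 40.0,
    amplitude: float = 0.5,
    ramp_ms: float = 0.5,
    lead_ms: float = 20.0,
    tail_ms: float = 20.0,
    jump_min_khz: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render syllable plans to a waveform with an exact truth table.

    Each plan is a list of ``(frequency_khz, duration_ms)`` note plateaus;
    notes are constant-frequency sinusoids with raised-cosine onset/offset
    ramps and abut within a syllable. White Gaussian noise is added at
    ``snr_db`` relative to the tone power (None for noiseless). The truth
    table carries exact onsets, offsets and labels derived from the planned
    jumps.
    """
    rng = np.random.default_rng(rng)
    plans = [list(p) for p in plans]
    max_f = max((f for p in plans for f, _ in p), default=0.0)
    if max_f * 1000.0 * 2.0 > rate:
        raise ValueError(
            f"sampling rate {rate:g} Hz below Nyquist for {max_f:g} kHz notes"
        )
    if snr_db is not None and not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite (or None for noiseless)")
    n_gaps = max(len(plans) - 1, 0)
    if np.isscalar(gaps_ms):
        gaps = [float(gaps_ms)] * n_gaps
    else:
        gaps = [float(g) for g in gaps_ms]
        if len(gaps) != n_gaps:
            raise ValueError(f"need {n_gaps} gaps for {len(plans)} syllables")
    if any(g <= 0 for g in gaps):
        raise ValueError("inter-syllable gaps must be positive")

    def n_samples(ms: float) -> int:
        return int(round(ms * rate / 1000.0))

    pieces: list[np.ndarray] = [np.zeros(n_samples(lead_ms))]
    t_cursor = lead_ms / 1000.0
    rows = []
    for k, plan in enumerate(plans):
        if not plan or any(d <= 0 or f <= 0 for f, d in plan):
            raise ValueError("every note needs positive frequency and duration")
        onset = t_cursor
        for f_khz, dur in plan:
            n = n_samples(dur)
            t = np.arange(n) / rate
            tone = amplitude * np.sin(2.0 * np.pi * f_khz * 1000.0 * t)
            n_ramp = min(n_samples(ramp_ms), n // 2)
            if n_ramp > 0:
                ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
                tone[:n_ramp] *= ramp
                tone[n - n_ramp:] *= ramp[::-1]
            pieces.append(tone)
            t_cursor += n / rate
        rows.append(
            {
                "onset_s": onset,
                "offset_s": t_cursor,
                "label": _label_from_plan(plan, jump_min_khz),
                "n_notes": len(plan),
            }
        )
        if k < len(plans) - 1:
            pieces.append(np.zeros(n_samples(gaps[k])))
            t_cursor += n_samples(gaps[k]) / rate
    pieces.append(np.zeros(n_samples(tail_ms)))
    wave = np.concatenate(pieces)
    if snr_db is not None:
        signal_power = amplitude**2 / 2.0
        noise_std = np.sqrt(signal_power / 10.0 ** (snr_db / 10.0))
        wave = wave + rng.normal(0.0, noise_std, wave.size)
    truth = pd.DataFrame(rows, columns=["onset_s", "offset_s", "label", "n_notes"])
    return wave, truth


def random_syllable_plans(
    n: int,
    rng: np.random.Generator | int | None = None,
    *,
    band_khz: tuple[float, float] = (45.0, 115.0),
    jump_khz: tuple[float, float] = (20.0, 35.0),
    note_ms: tuple[float, float] = (15.0, 30.0),
) -> tuple[list[list[tuple[float, float]]], list[str]]:
    """Random note plans cycling through the four syllable types.

    Jump magnitudes default to at least twice the 10 kHz detection
    threshold and all plateaus stay inside the analysis band. Returns
    ``(plans, intended_labels)``.
    """
    rng = np.random.default_rng(rng)
    lo, hi = band_khz
    plans: list[list[tuple[float, float]]] = []
    labels: list[str] = []
    kinds = ["s", "u", "d", "m"]
    for i in range(n):
        kind = kinds[i % 4]
        dur = lambda: float(rng.uniform(*note_ms))  # noqa: E731
        jump = float(rng.uniform(*jump_khz))
        if kind == "s":
            f = float(rng.uniform(lo, hi))
            plan = [(f, dur())]
        elif kind == "u":
            f = float(rng.uniform(lo, hi - jump))
            plan = [(f, dur()), (f + jump, dur())]
        elif kind == "d":
            f = float(rng.uniform(lo + jump, hi))
            plan = [(f, dur()), (f - jump, dur())]
        else:
            up_first = bool(rng.integers(2))
            if up_first:
                f = float(rng.uniform(lo, hi - jump))
                f2 = f + jump
                jump2 = float(rng.uniform(jump_khz[0], min(jump_khz[1], f2 - lo)))
                plan = [(f, dur()), (f2, dur()), (f2 - jump2, dur())]
            else:
                f = float(rng.uniform(lo + jump, hi))
                f2 = f - jump
                jump2 = float(rng.uniform(jump_khz[0], min(jump_khz[1], hi - f2)))
                plan = [(f, dur()), (f2, dur()), (f2 + jump2, dur())]
        plans.append(plan)
        labels.append(kind)
    return plans, labels
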