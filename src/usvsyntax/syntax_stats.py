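"""Markov transition probabilities and the two-stage syntax test.

The syllable alphabet is {s, d, u, m} plus silence (``X``). Each song bout
"a1...aL" contributes the transitions X->a1, a_i->a_{i+1}, aL->X, so a bout
of length L contributes L + 1 transitions. Excluding the structural X->X
pair leaves 24 transition types. Conditional transition probabilities are
row-normalized counts: P(start -> end) = count(start -> end) / total count
of transitions leaving ``start``.

Group differences in transition dynamics are tested in two stages:

1. *Local* tests — one two-sided rank test per transition type on the
   per-animal probabilities: Wilcoxon signed-rank (WSR) for paired
   within-group context comparisons, Wilcoxon-Mann-Whitney (WMW) for
   two-sample between-group comparisons. Exact enumeration (mid-ranks, all
   sign patterns / label assignments) is used for small samples, a normal
   approximation with tie and continuity corrections beyond that.
2. *Combined* tests — local p-values are combined with the truncated
   product method (TPM): W = product of the p-values at or below a
   truncation point tau (tau = 1 recovers Fisher's method). Combined
   statistics are formed for all transitions *to* each state, *from* each
   state, and globally over all 24. Their null distributions come from a
   Monte-Carlo permutation of whole animals (group-label shuffles, or
   per-animal context swaps in the paired design), which preserves the
   correlation among the local p-values. The to/from combined p-values are
   finally Benjamini-Hochberg adjusted across states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STATES",
    "SILENCE",
    "TRANSITIONS",
    "TransitionCounts",
    "SyntaxTestResult",
    "TpmResult",
    "transition_counts",
    "conditional_probabilities",
    "group_mean_probabilities",
    "wsr_pvalue",
    "wmw_pvalue",
    "local_tests_paired",
    "local_tests_two_sample",
    "combine_pvalues_tpm",
    "tpm_pvalue_montecarlo",
    "fisher_pvalue",
    "permutation_test",
    "compare_two_sample",
    "compare_paired",
    "fdr_adjust",
    "heatmap_table",
]

STATES: tuple[str, ...] = ("s", "d", "u", "m", "X")
SILENCE = "X"
_X = STATES.index(SILENCE)
_STATE_IDX = {s: i for i, s in enumerate(STATES)}

#: The 24 transition types: all ordered state pairs except silence->silence.
TRANSITIONS: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in STATES for b in STATES if not (a == SILENCE and b == SILENCE)
)
_TRANS_I = np.array([_STATE_IDX[a] for a, _ in TRANSITIONS])
_TRANS_J = np.array([_STATE_IDX[b] for _, b in TRANSITIONS])

#: Exact rank-test enumeration is used up to this many effective values.
EXACT_MAX_N = 12


@dataclass
class TransitionCounts:
    """Transition counts for one animal in one context."""

    counts: np.ndarray  # (5, 5) integers; (X, X) structurally zero
    animal_id: str = ""
    context: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5):
            raise ValueError("counts must be a 5x5 matrix over (s, d, u, m, X)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts[_X, _X] != 0:
            raise ValueError("the silence->silence cell is structurally excluded")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def transition_counts(
    coded: Iterable[str], animal_id: str = "", context: str = ""
) -> TransitionCounts:
    """Count transitions in a letter-coded corpus of song bouts.

    Each bout contributes silence->first, all internal pairs, and
    last->silence, so its transition total is its length plus one.
    """
    counts = np.zeros((5, 5), dtype=np.int64)
    for seq in coded:
        states = []
        for c in seq:
            if c not in _STATE_IDX or c == SILENCE:
                raise ValueError(f"invalid syllable label {c!r} in sequence {seq!r}")
            states.append(_STATE_IDX[c])
        if not states:
            continue
        path = [_X, *states, _X]
        for a, b in zip(path[:-1], path[1:]):
            counts[a, b] += 1
    return TransitionCounts(counts=counts, animal_id=animal_id, context=context)


def conditional_probabilities(counts: TransitionCounts | np.ndarray) -> np.ndarray:
    """Row-normalize counts into conditional transition probabilities.

    Each defined row sums to 1; rows whose start state never occurred are
    all-NaN, and the structural silence->silence cell is always NaN.
    """
    c = counts.counts if isinstance(counts, TransitionCounts) else np.asarray(counts)
    c = c.astype(np.float64)
    totals = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = c / totals[:, None]
    p[totals == 0] = np.nan
    p[_X, _X] = np.nan
    return p


def group_mean_probabilities(
    matrices: Sequence[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise unweighted mean over animals, skipping undefined rows.

    Returns ``(mean, n)`` where ``n`` counts the animals contributing to
    each cell; cells with no contributing animal are NaN.
    """
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    defined = ~np.isnan(stack)
    n = defined.sum(axis=0)
    total = np.where(defined, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / n
    mean[n == 0] = np.nan
    return mean, n


# ---------------------------------------------------------------------------
# Local rank tests


def _twosided_exact_p(obs: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
    """Two-sided p = min(1, 2 * min(P(T <= t), P(T >= t))) against an exact null."""
    obs = np.atleast_1d(np.asarray(obs, dtype=float))
    m = null_sorted.size
    le = np.searchsorted(null_sorted, obs + 1e-9, side="right")
    ge = m - np.searchsorted(null_sorted, obs - 1e-9, side="left")
    return np.minimum(1.0, 2.0 * np.minimum(le, ge) / m)


def _signed_rank_null(ranks: np.ndarray) -> np.ndarray:
    """W+ over all 2^m sign assignments of the ranked absolute differences."""
    m = ranks.size
    patterns = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
    return np.sort(patterns @ ranks)


def _ranksum_null(ranks: np.ndarray, n1: int) -> np.ndarray:
    """Group-1 rank sum over all assignments of n1 labels to the pooled ranks."""
    idx = np.array(list(itertools.combinations(range(ranks.size), n1)))
    return np.sort(ranks[idx].sum(axis=1))


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float((counts**3 - counts).sum())


def wsr_pvalue(diffs: Sequence[float], exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Missing pairs and zero differences are dropped; with fewer than two
    informative pairs the result is NaN (no local test). Exact enumeration
    of all sign patterns up to ``exact_max_n`` informative pairs, then a
    normal approximation with tie correction and 0.5 continuity correction.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0]
    m = d.size
    if m < 2:
        return float("nan")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if m <= exact_max_n:
        return float(_twosided_exact_p(w, _signed_rank_null(ranks))[0])
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - _tie_term(np.abs(d)) / 48.0
    if var <= 0:
        return 1.0
    z = max(abs(w - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def wmw_pvalue(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = EXACT_MAX_N
) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value for two independent samples.

    NaNs are dropped; fewer than two values in either group gives NaN.
    Exact enumeration over all label assignments (mid-ranks, so ties are
    handled) up to a pooled size of ``exact_max_n``, then the mid-rank
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        return float("nan")
    pooled = np.concatenate([x, y])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    if n <= exact_max_n:
        return float(_twosided_exact_p(r1, _ranksum_null(ranks, n1))[0])
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = max(abs(r1 - mu) - 0.5, 0.0) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def _cells(mats: np.ndarray) -> np.ndarray:
    """(n_animals, 5, 5) -> (n_animals, 24) in TRANSITIONS order."""
    return mats[:, _TRANS_I, _TRANS_J]


def _stack_matrices(matrices: Sequence[np.ndarray]) -> np.ndarray:
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    if stack.ndim != 3 or stack.shape[1:] != (5, 5):
        raise ValueError("expected a sequence of 5x5 probability matrices")
    return stack


def _to_matrix(pvec: np.ndarray) -> np.ndarray:
    out = np.full((5, 5), np.nan)
    out[_TRANS_I, _TRANS_J] = pvec
    return out


def local_tests_paired(
    matrices_a: Sequence[np.ndarray],
    matrices_b: Sequence[np.ndarray],
    animal_ids_a: Sequence[str] | None = None,
    animal_ids_b: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-transition WSR p-values between two contexts of the same animals.

    Inputs are aligned per-animal probability matrices. Returns a (5, 5)
    matrix of p-values with NaN at the silence->silence cell and wherever
    fewer than two informative pairs exist.
    """
    if animal_ids_a is not None and animal_ids_b is not None:
        if list(animal_ids_a) != list(animal_ids_b):
            raise ValueError("paired comparison requires the same animals in both contexts")
    a = _stack_matrices(matrices_a)
    b = _stack_matrices(matrices_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("paired comparison requires equally many animals per context")
    d = _cells(a) - _cells(b)
    return _to_matrix(np.array([wsr_pvalue(d[:, j]) for j in range(len(TRANSITIONS))]))


def local_tests_two_sample(
    matrices_1: Sequence[np.ndarray], matrices_2: Sequence[np.ndarray]
) -> np.ndarray:
    """Per-transition WMW p-values between two independent animal groups."""
    v1 = _cells(_stack_matrices(matrices_1))
    v2 = _cells(_stack_matrices(matrices_2))
    return _to_matrix(
        np.array([wmw_pvalue(v1[:, j], v2[:, j]) for j in range(len(TRANSITIONS))])
    )


# ---------------------------------------------------------------------------
# Truncated product method


class TpmResult(NamedTuple):
    w: float
    k_used: int  # p-values entering the product (p <= tau)
    n_valid: int  # non-missing p-values considered


def combine_pvalues_tpm(pvalues: Sequence[float], tau: float = 0.05) -> TpmResult:
    """Truncated product statistic W = prod of the p-values at or below tau.

    Missing p-values are excluded; an empty product gives W = 1. Smaller W
    is stronger evidence. If every input is missing the statistic is NaN.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        return TpmResult(float("nan"), 0, 0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    kept = p[p <= tau]
    w = float(np.prod(kept)) if kept.size else 1.0
    return TpmResult(w, int(kept.size), int(p.size))


def fisher_pvalue(w: float, k: int) -> float:
    """Closed-form combined p for W = product of k independent uniform
    p-values (tau = 1): the chi-square tail of -2 ln W on 2k df."""
    if w >= 1.0:
        return 1.0
    return float(stats.chi2.sf(-2.0 * np.log(w), 2 * k))


def tpm_pvalue_montecarlo(
    w_obs: float,
    k: int,
    tau: float = 0.05,
    n_draws: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo P(W <= w_obs) under k independent uniform p-values.

    This is the TPM's null under independence; with tau = 1 it converges to
    :func:`fisher_pvalue`. Uses the add-one estimator."""
    rng = np.random.default_rng(rng)
    u = rng.random((n_draws, k))
    w_null = np.where(u <= tau, u, 1.0).prod(axis=1)
    return (1 + int(np.sum(w_null <= w_obs + 1e-15))) / (1 + n_draws)


# ---------------------------------------------------------------------------
# Permutation machinery


def _local_p_two_sample(values: np.ndarray, group1: np.ndarray) -> np.ndarray:
    """WMW p-values for every permutation row and transition cell.

    ``values``: (n_animals, 24) per-animal probabilities (NaN = undefined
    row). ``group1``: (n_rows, n_animals) boolean group-1 membership, row 0
    being the observed labeling. Cells where either group has fewer than
    two defined animals are NaN for that row.
    """
    n_rows = group1.shape[0]
    out = np.full((n_rows, values.shape[1]), np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        dj = ~np.isnan(col)
        n = int(dj.sum())
        if n < 4:
            continue
        vals = col[dj]
        ranks = stats.rankdata(vals)
        gd = group1[:, dj]
        n1e = gd.sum(axis=1)
        n2e = n - n1e
        r1 = gd @ ranks
        valid = (n1e >= 2) & (n2e >= 2)
        if n <= EXACT_MAX_N:
            for k in np.unique(n1e[valid]):
                rows = valid & (n1e == k)
                out[rows, j] = _twosided_exact_p(r1[rows], _ranksum_null(ranks, int(k)))
        else:
            tie = _tie_term(vals)
            mu = n1e * (n + 1) / 2.0
            var = n1e * n2e / 12.0 * ((n + 1) - tie / (n * (n - 1)))
            degenerate = valid & (var <= 0)
            ok = valid & (var > 0)
            z = np.maximum(np.abs(r1[ok] - mu[ok]) - 0.5, 0.0) / np.sqrt(var[ok])
            out[ok, j] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
            out[degenerate, j] = 1.0
    return out


def _local_p_paired(diffs: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """WSR p-values for every sign-flip row and transition cell.

    ``diffs``: (n_animals, 24) paired differences (NaN = missing pair).
    ``signs``: (n_rows, n_animals) in {-1, +1}, row 0 all +1 (observed).
    Sign flips leave |d| (hence the ranks and the exact null) unchanged,
    so each permutation only relocates W+ within the same null.
    """
    n_rows = signs.shape[0]
    out = np.full((n_rows, diffs.shape[1]), np.nan)
    for j in range(diffs.shape[1]):
        dj = diffs[:, j]
        mask = ~np.isnan(dj) & (dj != 0)
        m = int(mask.sum())
        if m < 2:
            continue
        dd = dj[mask]
        ranks = stats.rankdata(np.abs(dd))
        pos = (signs[:, mask] * np.sign(dd)) > 0
        w = pos @ ranks
        if m <= EXACT_MAX_N:
            out[:, j] = _twosided_exact_p(w, _signed_rank_null(ranks))
        else:
            mu = m * (m + 1) / 4.0
            var = m * (m + 1) * (2 * m + 1) / 24.0 - _tie_term(np.abs(dd)) / 48.0
            if var <= 0:
                out[:, j] = 1.0
            else:
                z = np.maximum(np.abs(w - mu) - 0.5, 0.0) / np.sqrt(var)
                out[:, j] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    return out


def _target_indices() -> dict[str, np.ndarray]:
    targets: dict[str, np.ndarray] = {"global": np.arange(len(TRANSITIONS))}
    for s in STATES:
        targets[f"to:{s}"] = np.flatnonzero(_TRANS_J == _STATE_IDX[s])
        targets[f"from:{s}"] = np.flatnonzero(_TRANS_I == _STATE_IDX[s])
    return targets


_TARGETS = _target_indices()


def _tpm_rows(pmat: np.ndarray, idx: np.ndarray, tau: float) -> np.ndarray:
    """TPM statistic per permutation row over a subset of transition cells.

    Missing local p-values are excluded from the product symmetrically:
    the same NaN cells are skipped in the observed and every permuted row.
    """
    sub = pmat[:, idx]
    defined = ~np.isnan(sub)
    w = np.where(defined & (sub <= tau), sub, 1.0).prod(axis=1)
    w[defined.sum(axis=1) == 0] = np.nan
    return w


def _perm_pvalue(w: np.ndarray) -> float:
    """Add-one Monte-Carlo p: (1 + #{W_perm <= W_obs}) / (1 + n_perm)."""
    if np.isnan(w[0]):
        return float("nan")
    perm = w[1:]
    perm = perm[~np.isnan(perm)]
    return (1 + int(np.sum(perm <= w[0] + 1e-15))) / (1 + perm.size)


@dataclass
class SyntaxTestResult:
    """Result of one two-stage syntax comparison."""

    comparison: str
    local_p: np.ndarray  # (5, 5); NaN at (X, X) and untestable cells
    to_p: dict[str, float]
    from_p: dict[str, float]
    global_p: float
    to_p_adjusted: dict[str, float] = field(default_factory=dict)
    from_p_adjusted: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int = 0
    tau: float = 0.05

    def to_json_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "states": list(STATES),
            "local_p": [
                [None if np.isnan(v) else float(v) for v in row]
                for row in self.local_p
            ],
            "to_p": {k: _jsonable(v) for k, v in self.to_p.items()},
            "from_p": {k: _jsonable(v) for k, v in self.from_p.items()},
            "global_p": _jsonable(self.global_p),
            "to_p_adjusted": {k: _jsonable(v) for k, v in self.to_p_adjusted.items()},
            "from_p_adjusted": {
                k: _jsonable(v) for k, v in self.from_p_adjusted.items()
            },
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "tau": self.tau,
        }


def _jsonable(v: float) -> float | None:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def _assemble_result(
    comparison: str,
    pmat: np.ndarray,
    tau: float,
    n_perm: int,
    seed: int,
    fdr_family: str,
) -> SyntaxTestResult:
    to_p, from_p = {}, {}
    global_p = float("nan")
    for name, idx in _TARGETS.items():
        p = _perm_pvalue(_tpm_rows(pmat, idx, tau))
        if name == "global":
            global_p = p
        elif name.startswith("to:"):
            to_p[name[3:]] = p
        else:
            from_p[name[5:]] = p
    if fdr_family == "margins":
        adj = fdr_adjust([*to_p.values(), *from_p.values()])
        to_adj = dict(zip(to_p, adj[:5]))
        from_adj = dict(zip(from_p, adj[5:]))
    elif fdr_family == "separate":
        to_adj = dict(zip(to_p, fdr_adjust(list(to_p.values()))))
        from_adj = dict(zip(from_p, fdr_adjust(list(from_p.values()))))
    elif fdr_family == "none":
        to_adj, from_adj = dict(to_p), dict(from_p)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return SyntaxTestResult(
        comparison=comparison,
        local_p=_to_matrix(pmat[0]),
        to_p=to_p,
        from_p=from_p,
        global_p=global_p,
        to_p_adjusted=to_adj,
        from_p_adjusted=from_adj,
        n_permutations=n_perm,
        seed=seed,
        tau=tau,
    )


def compare_two_sample(
    matrices_1: Sequence[np.ndarray],
    matrices_2: Sequence[np.ndarray],
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    tau: float = 0.05,
    fdr_family: str = "margins",
    comparison: str = "two-sample",
) -> SyntaxTestResult:
    """Between-group syntax comparison within one context.

    The permutation unit is the animal: each of ``n_perm`` permutations
    reshuffles the group labels over all animals and recomputes every local
    WMW test and combined statistic identically, so the null respects the
    correlation among local p-values.
    """
    v1 = _cells(_stack_matrices(matrices_1))
    v2 = _cells(_stack_matrices(matrices_2))
    n1, n2 = v1.shape[0], v2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("two-sample comparison needs at least 2 animals per group")
    values = np.vstack([v1, v2])
    rng = np.random.default_rng(seed)
    group1 = np.zeros((n_perm + 1, n1 + n2), dtype=bool)
    group1[0, :n1] = True
    for b in range(1, n_perm + 1):
        group1[b, rng.permutation(n1 + n2)[:n1]] = True
    pmat = _local_p_two_sample(values, group1)
    return _assemble_result(comparison, pmat, tau, n_perm, seed, fdr_family)


def compare_paired(
    matrices_a: Sequence[np.ndarray],
    matrices_b: Sequence[np.ndarray],
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    tau: float = 0.05,
    fdr_family: str = "margins",
    comparison: str = "paired",
    animal_ids_a: Sequence[str] | None = None,
    animal_ids_b: Sequence[str] | None = None,
) -> SyntaxTestResult:
    """Within-group syntax comparison between two contexts (paired).

    Permutations swap the two contexts independently per animal (a sign
    flip of that animal's 24 paired differences), recomputing all local WSR
    tests and combined statistics per flip pattern.
    """
    if animal_ids_a is not None and animal_ids_b is not None:
        if list(animal_ids_a) != list(animal_ids_b):
            raise ValueError("paired comparison requires the same animals in both contexts")
    a = _stack_matrices(matrices_a)
    b = _stack_matrices(matrices_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("paired comparison requires equally many animals per context")
    n = a.shape[0]
    if n < 2:
        raise ValueError("paired comparison needs at least 2 animals")
    diffs = _cells(a) - _cells(b)
    rng = np.random.default_rng(seed)
    signs = np.ones((n_perm + 1, n), dtype=np.int8)
    signs[1:] = rng.choice(np.array([-1, 1], dtype=np.int8), size=(n_perm, n))
    pmat = _local_p_paired(diffs, signs)
    return _assemble_result(comparison, pmat, tau, n_perm, seed, fdr_family)


def permutation_test(
    matrices_1: Sequence[np.ndarray],
    matrices_2: Sequence[np.ndarray],
    target: str = "global",
    *,
    kind: str = "two-sample",
    n_perm: int = 10_000,
    seed: int = 0,
    tau: float = 0.05,
) -> float:
    """Permutation p-value for one combined target.

    ``target`` is ``"global"``, ``"to:<state>"`` or ``"from:<state>"``
    (states s, d, u, m, X).
    """
    if target not in _TARGETS:
        raise ValueError(f"unknown target {target!r}; one of {sorted(_TARGETS)}")
    fn = compare_two_sample if kind == "two-sample" else compare_paired
    res = fn(matrices_1, matrices_2, n_perm=n_perm, seed=seed, tau=tau, fdr_family="none")
    if target == "global":
        return res.global_p
    kind_, state = target.split(":")
    return (res.to_p if kind_ == "to" else res.from_p)[state]


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def heatmap_table(result: SyntaxTestResult) -> pd.DataFrame:
    """Rectangular p-value table: rows = start states, columns = end states,
    a ``from_combined`` margin column, a ``to_combined`` margin row, and the
    global p in the corner. Serializes to/from CSV losslessly."""
    rows = [*STATES, "to_combined"]
    cols = [*STATES, "from_combined"]
    table = pd.DataFrame(np.nan, index=rows, columns=cols)
    table.loc[list(STATES), list(STATES)] = result.local_p
    for s in STATES:
        table.loc[s, "from_combined"] = result.from_p.get(s, np.nan)
        table.loc["to_combined", s] = result.to_p.get(s, np.nan)
    table.loc["to_combined", "from_combined"] = result.global_p
    table.index.name = "start"
    return table
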