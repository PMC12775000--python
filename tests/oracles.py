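"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the score
distribution is enumerated over all 4**L sequences, and the two-sided
binomial p-value is enumerated over all n+1 outcomes in exact rational
arithmetic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def enumerate_score_distribution(log_odds: np.ndarray, background, grid_step: float):
    """Distribution of grid-floored PWM scores over all 4**L sequences.

    Matches the DP's rounding: each per-position log-odds value is
    floored to an integer multiple of grid_step before summation.
    Returns (support_grid_indices, probabilities) sorted ascending.
    """
    L = log_odds.shape[1]
    idx = np.floor(np.asarray(log_odds) / grid_step).astype(np.int64)
    bg = np.asarray(background, dtype=float)
    acc: dict[int, float] = {}
    for bases in itertools.product(range(4), repeat=L):
        g = int(sum(idx[b, i] for i, b in enumerate(bases)))
        p = float(np.prod([bg[b] for b in bases]))
        acc[g] = acc.get(g, 0.0) + p
    support = np.array(sorted(acc))
    mass = np.array([acc[s] for s in support])
    return support, mass / mass.sum()


def enumerate_exact_scores(log_odds: np.ndarray) -> np.ndarray:
    """Exact (un-floored) scores of all 4**L sequences, vectorized."""
    L = log_odds.shape[1]
    grids = np.meshgrid(*[np.arange(4)] * L, indexing="ij")
    total = np.zeros(4**L)
    for i, g in enumerate(grids):
        total += np.asarray(log_odds)[g.ravel(), i]
    return total


def exact_minlike(k: int, n: int, p0: Fraction) -> float:
    """Two-sided minlike binomial p-value by exact rational enumeration."""
    p0 = Fraction(p0)
    pmf = [comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    obs = pmf[k]
    return float(sum(p for p in pmf if p <= obs))


def best_hit_score_bruteforce(log_odds: np.ndarray, window: str, variant_offset: int):
    """Best placement score covering the variant, both strands, by direct
    enumeration (independent of scan_allele's loop structure)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    lo_mat = np.asarray(log_odds)
    L = lo_mat.shape[1]
    best = -np.inf
    for off in range(0, len(window) - L + 1):
        if not off <= variant_offset <= off + L - 1:
            continue
        piece = window[off : off + L]
        rc = "".join(comp[b] for b in reversed(piece))
        for seq in (piece, rc):
            s = sum(lo_mat[base_idx[b], i] for i, b in enumerate(seq))
            best = max(best, s)
    return best
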