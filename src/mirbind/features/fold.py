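"""Lightweight local secondary-structure backend.

A Nussinov-style partition function over a local window: every admissible
base pair (Watson-Crick or G:U wobble, minimum hairpin loop of 3) contributes
a Boltzmann weight from a per-pair energy, and an inside/outside pass yields
exact pair probabilities under that model.  From these we report per-base
unpaired propensities and the opening energy of a site (free-energy cost of
forcing all site bases unpaired).  This is deliberately a simplified energy
model — no stacking-loop thermodynamics — standing in for a full folding tool
behind the same interface.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np

RT_37C = 0.6163  # kcal/mol

_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def _weight_matrix(seq: str, rt: float, min_loop: int) -> np.ndarray:
    n = len(seq)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            e = _PAIR_ENERGY.get((seq[i], seq[j]))
            if e is not None:
                w[i, j] = math.exp(-e / rt)
    return w


def _inside(w: np.ndarray, min_loop: int) -> np.ndarray:
    # A[i, j+1] = partition function of segment [i..j]; empty segments = 1.
    n = w.shape[0]
    A = np.zeros((n + 2, n + 2))
    for i in range(n + 2):
        for j in range(i + 1):
            A[i, j] = 1.0
    for length in range(1, n + 1):
        for i in range(n - length + 1):
            j = i + length - 1
            total = A[i + 1, j + 1]
            for k in range(i + min_loop + 1, j + 1):
                if w[i, k] > 0.0:
                    total += w[i, k] * A[i + 1, k] * A[k + 1, j + 1]
            A[i, j + 1] = total
    return A


def _pair_probs(w: np.ndarray, A: np.ndarray, min_loop: int) -> np.ndarray:
    # Outside pass; accumulates P[i, k] = probability that (i, k) is paired.
    n = w.shape[0]
    X = np.zeros((n + 2, n + 2))
    P = np.zeros((n, n))
    X[0, n] = 1.0
    z_total = A[0, n]
    for length in range(n, 0, -1):
        for i in range(n - length + 1):
            j = i + length - 1
            v = X[i, j + 1]
            if v == 0.0:
                continue
            X[i + 1, j + 1] += v
            for k in range(i + min_loop + 1, j + 1):
                if w[i, k] > 0.0:
                    contrib = v * w[i, k]
                    X[i + 1, k] += contrib * A[k + 1, j + 1]
                    X[k + 1, j + 1] += contrib * A[i + 1, k]
                    P[i, k] += contrib * A[i + 1, k] * A[k + 1, j + 1]
    return P / z_total


try:  # pragma: no cover - thin JIT wrapper
    from numba import njit

    _inside = njit(cache=True)(_inside)
    _pair_probs = njit(cache=True)(_pair_probs)
except Exception:  # numba unavailable: pure-python fallback is fine
    pass


class NussinovFoldBackend:
    """Local-window fold backend exposing unpaired propensity and opening energy."""

    def __init__(self, window: int = 25, rt: float = RT_37C, min_loop: int = 3):
        self.window = window
        self.rt = rt
        self.min_loop = min_loop

    def analyze(
        self, utr_seq: str, site_start: int, site_end: int
    ) -> Tuple[float, np.ndarray, int]:
        """Return (opening energy of the site, unpaired profile, window start).

        The profile covers the analysis window ``[window_start, window_end)``;
        profile[i] is the probability that window base i is unpaired.
        """
        lo = max(0, site_start - self.window)
        hi = min(len(utr_seq), site_end + self.window)
        seq = utr_seq[lo:hi]
        w = _weight_matrix(seq, self.rt, self.min_loop)
        A = _inside(w, self.min_loop)
        P = _pair_probs(w, A, self.min_loop)
        unpaired = 1.0 - (P.sum(axis=0) + P.sum(axis=1))
        # Constrain site bases to be unpaired and measure the cost.
        wc = w.copy()
        wc[site_start - lo:site_end - lo, :] = 0.0
        wc[:, site_start - lo:site_end - lo] = 0.0
        Ac = _inside(wc, self.min_loop)
        n = len(seq)
        opening = -self.rt * math.log(Ac[0, n] / A[0, n])
        return opening, np.clip(unpaired, 0.0, 1.0), lo
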