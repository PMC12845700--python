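"""Weighted multi-indicator selection of intrinsic mode functions.

A good mode carries most of the signal energy, correlates strongly with
the original signal, and has low complexity.  Each mode is therefore
scored by three indicators — energy ratio E, Pearson correlation rho with
the original signal, and sample entropy S — min-max normalised across the
K modes of a channel and combined as

    score = w_p * rho' + w_e * E' + w_s * (1 - S')

with fixed weights (w_p, w_e, w_s) = (0.4, 0.4, 0.2).  The top-N modes
per channel are retained (N = 1 by default, one mode per electrode).

The combination uses the normalised energy E' by default for consistency
with the normalisation of the other two indicators; ``use_raw_energy``
switches to the raw-E variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .vmd import VmdConfig, improved_vmd

DEFAULT_WEIGHTS = (0.4, 0.4, 0.2)   # (w_p, w_e, w_s)


@dataclass
class ImfIndicators:
    """Raw and normalised quality indicators of one mode."""

    energy_ratio: float
    pearson: float
    samp_entropy: float
    energy_norm: float = np.nan
    pearson_norm: float = np.nan
    entropy_norm: float = np.nan
    score: float = np.nan
    selected: bool = False


def sample_entropy(series: np.ndarray, m: int = 2,
                   r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    Counts template pairs (self-matches excluded) of lengths m and m+1
    within tolerance ``r`` (default 0.2 x SD of the series) and returns
    -ln(A/B).  When either count is zero the undefined logarithm is
    replaced by the sentinel ln(number of possible pairs), the largest
    value the estimator could have resolved.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise ValueError("series too short for the embedding dimension")
    if r is None:
        r = 0.2 * float(np.std(x))
    nt = n - m                     # templates considered for both lengths
    dmax = np.zeros((nt, nt))
    for k in range(m):
        dk = np.abs(x[k:k + nt, None] - x[None, k:k + nt])
        np.maximum(dmax, dk, out=dmax)
    iu = np.triu_indices(nt, k=1)
    B = int(np.count_nonzero(dmax[iu] <= r))
    np.maximum(dmax, np.abs(x[m:m + nt, None] - x[None, m:m + nt]),
               out=dmax)
    A = int(np.count_nonzero(dmax[iu] <= r))
    if A == 0 or B == 0:
        return float(np.log(nt * (nt - 1) / 2))
    return float(-np.log(A / B))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.full(values.shape, 0.5)   # neutral degenerate-range rule
    return (values - lo) / (hi - lo)


def compute_indicators(signal: np.ndarray, modes: np.ndarray,
                       entropy_m: int = 2) -> list[ImfIndicators]:
    """Energy ratio, Pearson correlation and sample entropy per mode."""
    x = np.asarray(signal, dtype=float).ravel()
    M = np.atleast_2d(np.asarray(modes, dtype=float))
    if M.shape[1] != x.size:
        raise ValueError("modes and signal lengths disagree")
    energies = np.sum(M * M, axis=1)
    tot = energies.sum()
    e = energies / tot if tot > 0 else np.zeros(M.shape[0])
    rho = np.empty(M.shape[0])
    sx = float(np.std(x))
    for i, mode in enumerate(M):
        sm = float(np.std(mode))
        if sm == 0.0 or sx == 0.0:
            warnings.warn("constant mode or signal: correlation set to 0")
            rho[i] = 0.0
        else:
            rho[i] = float(np.corrcoef(mode, x)[0, 1])
    ent = np.array([sample_entropy(mode, m=entropy_m) for mode in M])
    e_n, rho_n, ent_n = _minmax(e), _minmax(rho), _minmax(ent)
    return [
        ImfIndicators(energy_ratio=float(e[i]), pearson=float(rho[i]),
                      samp_entropy=float(ent[i]), energy_norm=float(e_n[i]),
                      pearson_norm=float(rho_n[i]),
                      entropy_norm=float(ent_n[i]))
        for i in range(M.shape[0])
    ]


def score_and_select(indicators: list[ImfIndicators],
                     weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                     n_select: int = 1,
                     use_raw_energy: bool = False
                     ) -> tuple[list[int], np.ndarray]:
    """Combine indicators into scores and pick the top-N mode indices.

    Ties are broken toward the lower mode index.  Scores are written back
    onto the indicator objects and the selected flags set.
    """
    K = len(indicators)
    if not np.isclose(sum(weights), 1.0):
        raise ValueError("weights must sum to 1")
    if not 1 <= n_select <= K:
        raise ValueError("n_select must lie in [1, K]")
    w_p, w_e, w_s = weights
    scores = np.empty(K)
    for i, ind in enumerate(indicators):
        e_term = ind.energy_ratio if use_raw_energy else ind.energy_norm
        scores[i] = (w_p * ind.pearson_norm + w_e * e_term
                     + w_s * (1.0 - ind.entropy_norm))
        ind.score = float(scores[i])
    ranked = np.argsort(-scores, kind="stable")     # stable: ties -> low idx
    chosen = [int(i) for i in ranked[:n_select]]
    for i in chosen:
        indicators[i].selected = True
    return chosen, scores


def select_mode(signal: np.ndarray, cfg: VmdConfig | None = None,
                fs: float = 1.0,
                weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                fallback_threshold: float = 0.1) -> np.ndarray:
    """Decompose one channel and return its top-scoring mode.

    On a quality fallback (poor reconstruction or non-convergence) the
    input signal itself is returned so downstream stages always receive a
    usable series.
    """
    res, qc = improved_vmd(signal, cfg, fs=fs,
                           fallback_threshold=fallback_threshold)
    if qc.fallback:
        return np.asarray(signal, dtype=float).copy()
    inds = compute_indicators(signal, res.modes)
    chosen, _ = score_and_select(inds, weights=weights, n_select=1)
    return res.modes[chosen[0]].copy()
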