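"""Straight-loop reference implementations for cross-validation.

Everything here trades speed for transparency: explicit per-position and
per-window loops, no vectorized shortcuts, no shared code with the optimized
paths beyond the data containers.  Tests assert that the optimized pipeline
reproduces these results exactly (to floating-point noise) on small tracks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_gaussian_smooth(
    values: np.ndarray, sigma: float, mass: float
) -> np.ndarray:
    """Spread each count with a truncated renormalized Gaussian, per position."""
    from scipy.stats import norm

    half = math.ceil(norm.ppf(0.5 + mass / 2.0) * sigma)
    offsets = list(range(-half, half + 1))
    base = [math.exp(-0.5 * (o / sigma) ** 2) for o in offsets]
    total = sum(base)
    kernel = [w / total for w in base]
    n = len(values)
    out = np.zeros(n)
    for p in range(n):
        if values[p] == 0:
            continue
        weights = []
        targets = []
        for o, w in zip(offsets, kernel):
            q = p + o
            if 0 <= q < n:
                weights.append(w)
                targets.append(q)
        in_mass = sum(weights)
        for q, w in zip(targets, weights):
            out[q] += values[p] * w / in_mass
    return out


def naive_window_rmsd(
    a: np.ndarray, b: np.ndarray, window: int, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window RMSD of unit-area-rescaled curves; zero-sum windows → 0."""
    n_win = (len(a) - window) // step + 1
    rmsd = np.zeros(n_win)
    zero = np.zeros(n_win, dtype=bool)
    for i in range(n_win):
        s = i * step
        wa = a[s : s + window]
        wb = b[s : s + window]
        sa, sb = wa.sum(), wb.sum()
        if sa == 0 or sb == 0:
            zero[i] = True
            continue
        diff = wa / sa - wb / sb
        rmsd[i] = math.sqrt(float((diff * diff).mean()))
    return rmsd, zero


def naive_percentile(pool, q: float) -> float:
    """Linear interpolation between order statistics (inclusive)."""
    xs = sorted(float(x) for x in pool)
    if not xs:
        raise ValueError("empty pool")
    if len(xs) == 1:
        return xs[0]
    pos = q / 100.0 * (len(xs) - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def naive_local_maxima(values: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus collapse to the middle index.

    A run strictly above both neighbouring runs is a peak; runs touching the
    series ends never are.
    """
    n = len(values)
    runs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        runs.append((i, j, values[i]))
        i = j + 1
    peaks = []
    for k in range(1, len(runs) - 1):
        lo, hi, v = runs[k]
        if v > runs[k - 1][2] and v > runs[k + 1][2]:
            peaks.append((lo + hi) // 2)
    return peaks


def naive_contig(diff: np.ndarray, peak: int, threshold: float) -> tuple[int, int]:
    """Inclusive [lo, hi] span: widen while per-position diff >= threshold."""
    lo = peak
    while lo > 0 and diff[lo - 1] >= threshold:
        lo -= 1
    hi = peak
    while hi < len(diff) - 1 and diff[hi + 1] >= threshold:
        hi += 1
    return lo, hi


def naive_fisher_two_sided(k: int, n: int, K: int, N: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Fixed margins: row totals (n, N), column total of successes k + K.
    Sums the probabilities of every table at most as probable as the observed
    one (with a tiny relative slack for floating-point ties).
    """
    total = n + N
    successes = k + K
    log_fact = [0.0]
    for i in range(1, total + 1):
        log_fact.append(log_fact[-1] + math.log(i))

    def log_comb(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -math.inf
        return log_fact[a] - log_fact[b] - log_fact[a - b]

    denom = log_comb(total, successes)

    def prob(x: int) -> float:
        lp = log_comb(n, x) + log_comb(N, successes - x) - denom
        return math.exp(lp) if lp > -math.inf else 0.0

    p_obs = prob(k)
    p = 0.0
    for x in range(0, successes + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-10):
            p += px
    return min(p, 1.0)


def naive_pwm_best(seq: str, weights: np.ndarray) -> tuple[float, int, str]:
    """Best PWM score over all offsets and both strands, by full enumeration."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = weights.shape[0]
    best = (-math.inf, -1, "+")
    for strand in ("+", "-"):
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            if strand == "-":
                window = "".join(comp.get(b, "N") for b in reversed(window))
            score = 0.0
            for j, b in enumerate(window):
                if b in idx:
                    score += weights[j, idx[b]]
                else:
                    score += weights[j].min()
            if score > best[0]:
                best = (score, off, strand)
    return best


def naive_scan_hits(
    seq: str, weights: np.ndarray, threshold_frac: float
) -> list[tuple[int, str, float]]:
    """All (offset, strand, score) with relative score strictly above cutoff."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = weights.shape[0]
    min_s = float(weights.min(axis=1).sum())
    max_s = float(weights.max(axis=1).sum())
    hits = []
    for strand in ("+", "-"):
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            if strand == "-":
                window = "".join(comp.get(b, "N") for b in reversed(window))
            score = 0.0
            for j, b in enumerate(window.upper()):
                if b in idx:
                    score += weights[j, idx[b]]
                else:
                    score += weights[j].min()
            if (score - min_s) / (max_s - min_s) > threshold_frac:
                hits.append((off, strand, score))
    return hits


__all__ = [
    "naive_contig",
    "naive_fisher_two_sided",
    "naive_gaussian_smooth",
    "naive_local_maxima",
    "naive_percentile",
    "naive_pwm_best",
    "naive_scan_hits",
    "naive_window_rmsd",
]
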