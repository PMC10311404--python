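"""Independent test oracles: a minimal Kingman coalescent and classic
summary statistics, implemented directly from their textbook definitions.

These deliberately share no code with the package: the coalescent here is
a plain O(n) lineage-merging simulation without recombination (with
optional piecewise-constant population size), and the statistics are
computed by direct enumeration.  They exist so the package's simulator
can be checked against an implementation that cannot share its bugs.
"""

from __future__ import annotations

import numpy as np


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's constant)."""
    return sum(1.0 / i for i in range(1, n))


def kingman_segsites(
    n: int,
    theta: float,
    n_reps: int,
    rng: np.random.Generator,
    epochs: tuple[tuple[float, float], ...] = (),
) -> np.ndarray:
    """Segregating-site counts under the neutral coalescent, no recombination.

    Time is measured in units of 4N0 generations (so the pairwise
    coalescence rate for k lineages is k(k-1)/2 per 2N0 generations,
    i.e. k(k-1) per unit here... we instead work in units of 2N0
    generations where the rate is k(k-1)/2 and E[total length] =
    2*sum 1/i, giving E[S] = theta/2 * E[L] = theta * a_n).

    ``epochs`` is a list of (time-in-4N0-generations, relative-size)
    step changes, as in the package's configuration; internally times
    are converted to 2N0 units (factor 2) and the coalescence rate in an
    epoch of relative size lambda is divided by lambda.
    """
    boundaries = [2.0 * t for t, _ in epochs]  # 4N0 -> 2N0 units
    sizes = [1.0] + [rel for _, rel in epochs]
    out = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        t = 0.0
        k = n
        total_len = 0.0
        epoch_i = 0
        while k > 1:
            rate = k * (k - 1) / 2.0 / sizes[epoch_i]
            wait = rng.exponential(1.0 / rate)
            # step through epoch boundaries with time rescaling
            while (epoch_i < len(boundaries)
                   and t + wait > boundaries[epoch_i]):
                frac = (boundaries[epoch_i] - t) / wait if wait > 0 else 0.0
                total_len += k * (boundaries[epoch_i] - t)
                t = boundaries[epoch_i]
                epoch_i += 1
                rate_new = k * (k - 1) / 2.0 / sizes[epoch_i]
                wait = rng.exponential(1.0 / rate_new)
            total_len += k * wait
            t += wait
            k -= 1
        # mutations: Poisson(theta/2 * total branch length in 2N0 units)
        out[r] = rng.poisson(theta / 2.0 * total_len)
    return out


# ---------------------------------------------------------------------------
# summary statistics by direct enumeration
# ---------------------------------------------------------------------------

def pairwise_diversity(haps: np.ndarray) -> float:
    """Mean number of pairwise differences (sum over sites of 2*d*(n-d) /
    (n*(n-1)))."""
    h = np.asarray(haps, dtype=float)
    n = h.shape[0]
    if n < 2 or h.shape[1] == 0:
        return 0.0
    d = h.sum(axis=0)
    return float((2 * d * (n - d) / (n * (n - 1))).sum())


def tajimas_d(haps: np.ndarray) -> float:
    """Tajima's D from the standard constants."""
    h = np.asarray(haps)
    n, s = h.shape
    if s == 0:
        return 0.0
    a1 = harmonic(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    if var <= 0:
        return 0.0
    return (pairwise_diversity(h) - s / a1) / np.sqrt(var)


def high_freq_derived_fraction(haps: np.ndarray, cutoff: float = 0.8) -> float:
    """Fraction of segregating sites whose derived allele frequency
    exceeds ``cutoff``."""
    h = np.asarray(haps, dtype=float)
    if h.shape[1] == 0:
        return 0.0
    freq = h.mean(axis=0)
    return float((freq > cutoff).mean())


def mean_r2(haps: np.ndarray, pairs: np.ndarray) -> float:
    """Mean r^2 over the given site-index pairs (LD by direct formula)."""
    h = np.asarray(haps, dtype=float)
    vals = []
    for i, j in pairs:
        p1, p2 = h[:, i].mean(), h[:, j].mean()
        if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
            continue
        d = (h[:, i] * h[:, j]).mean() - p1 * p2
        vals.append(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))
    return float(np.mean(vals)) if vals else 0.0


def brute_force_f1(true, pred) -> float:
    """Confusion-matrix F1 computed element by element."""
    tp = fp = fn = 0
    for t, p in zip(true, pred):
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 1:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
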