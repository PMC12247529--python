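"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, literal way (plain Python
loops, textbook formulas, exhaustive enumeration) and shares no code with
the package's own computation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


def overlap_counts_bruteforce(a, b):
    """Count |A∩B|, |A|, |B| by looping over flattened voxel lists."""
    inter = na = nb = 0
    for va, vb in zip(np.asarray(a).ravel().tolist(), np.asarray(b).ravel().tolist()):
        va, vb = int(bool(va)), int(bool(vb))
        inter += va * vb
        na += va
        nb += vb
    return inter, na, nb


def dice_bruteforce(a, b):
    inter, na, nb = overlap_counts_bruteforce(a, b)
    return 2.0 * inter / (na + nb)


def pseudo_dice_bruteforce(a, b, eps, variant):
    inter, na, nb = overlap_counts_bruteforce(a, b)
    if variant == "as_printed":
        return 2.0 * (inter + eps) / (na + nb + eps)
    return (2.0 * inter + eps) / (na + nb + eps)


def top_k_bruteforce(scores, k):
    """Best size-k subset of slice indices: maximize score sum, break ties
    by the lexicographically smallest index tuple. Exhaustive enumeration."""
    n = len(scores)
    k = min(k, n)
    best = None
    for combo in itertools.combinations(range(n), k):
        key = (sum(scores[i] for i in combo), tuple(-i for i in combo))
        # higher sum wins; among equal sums the lexicographically smaller
        # index tuple wins, i.e. the larger tuple of negated indices
        if best is None or key > best[0]:
            best = (key, combo)
    return list(best[1])


def mean_textbook(values):
    return sum(values) / len(values)


def sd_textbook(values):
    m = mean_textbook(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def median_textbook(values):
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def ci95_textbook(values):
    n = len(values)
    m = mean_textbook(values)
    half = sps.t.ppf(0.975, n - 1) * sd_textbook(values) / math.sqrt(n)
    return (m - half, m + half)


def paired_t_textbook(x, y):
    d = [xi - yi for xi, yi in zip(x, y)]
    n = len(d)
    t = mean_textbook(d) / (sd_textbook(d) / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return t, p, n - 1


def ellipsoid_voxel_count_bruteforce(shape, center, semi_axes):
    """Enumerate every voxel and test the ellipsoid inequality directly."""
    (cx, cy, cz), (ax, ay, az) = center, semi_axes
    count = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0:
                    count += 1
    return count
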