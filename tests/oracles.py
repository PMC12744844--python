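"""Independent brute-force oracles used by the tests.

Deliberately written with explicit Python loops and from-definition
formulas, sharing no code path with the package implementation.
"""

from __future__ import annotations

import itertools
import math


def brute_force_rmsd(coords_a, coords_b) -> float:
    """sqrt of mean squared distance over explicit per-atom loops."""
    assert len(coords_a) == len(coords_b) and len(coords_a) > 0
    total = 0.0
    for (xa, ya, za), (xb, yb, zb) in zip(coords_a, coords_b):
        dx = xa - xb
        dy = ya - yb
        dz = za - zb
        total += dx * dx + dy * dy + dz * dz
    return math.sqrt(total / len(coords_a))


def brute_force_distances(coords_a, coords_b):
    out = []
    for (xa, ya, za), (xb, yb, zb) in zip(coords_a, coords_b):
        out.append(math.sqrt((xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2))
    return out


def pearson_from_definition(xs, ys) -> float:
    """Covariance over the product of standard deviations, explicit loops."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sxx = syy = 0.0
    for x, y in zip(xs, ys):
        cov += (x - mx) * (y - my)
        sxx += (x - mx) ** 2
        syy += (y - my) ** 2
    return cov / math.sqrt(sxx * syy)


def ols_normal_equations(xs, ys):
    """(slope, intercept) from the closed-form normal equations."""
    n = len(xs)
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def ranksum_exact_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p by enumeration of all group assignments.

    Tie-free samples only; probability that |U - mean(U)| of a random
    assignment is at least as large as observed.
    """
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)
    n = len(pooled)
    obs = sum(ranks[v] for v in a)
    mean_w = n_a * (n + 1) / 2.0
    obs_dev = abs(obs - mean_w)
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), n_a):
        total += 1
        if abs(sum(combo) - mean_w) >= obs_dev - 1e-12:
            count += 1
    return count / total
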