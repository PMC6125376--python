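import numpy as np
import pytest

from oasig import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def separable_cohort():
    """Small balanced cohort with 5 strong planted genes and a null background."""
    spec = SyntheticSpec(
        n_case=30,
        n_control=30,
        n_informative=5,
        n_redundant_per_informative=1,
        n_null=200,
        effect_size=3.0,
        redundancy_noise_sd=0.1,
        seed=1,
    )
    em, truth = generate_cohort(spec)
    return em, truth


def naive_mi(x, y):
    """Cell-by-cell plug-in mutual information in bits (independent oracle)."""
    import math
    from collections import Counter

    n = len(x)
    assert len(y) == n
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        pab = c / n
        total += pab * math.log2(pab / ((px[a] / n) * (py[b] / n)))
    return total


def naive_mrmr(columns, labels, top_n):
    """Plain-Python greedy mRMR over a list of per-gene code sequences.

    Returns the list of selected column indices in rank order. Independent of
    the package implementation: recomputes the mean redundancy from scratch
    at every step.
    """
    n_genes = len(columns)
    candidates = list(range(n_genes))
    selected: list[int] = []
    for _ in range(top_n):
        scores = {}
        for j in candidates:
            rel = naive_mi(columns[j], labels)
            if selected:
                red = sum(naive_mi(columns[j], columns[s]) for s in selected) / len(
                    selected
                )
            else:
                red = 0.0
            scores[j] = rel - red
        mx = max(scores.values())
        # ties broken by input order; 1e-9 absorbs float summation-order noise
        best_j = next(j for j in candidates if scores[j] > mx - 1e-9)
        selected.append(best_j)
        candidates.remove(best_j)
    return selected


def naive_hypergeom_upper(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exhaustive enumeration."""
    from math import comb

    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total
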