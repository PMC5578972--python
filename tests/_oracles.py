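"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the AUROC oracle is the
literal O(m*n) double sum over case-control pairs, in exact rational
arithmetic.
"""

from fractions import Fraction

import numpy as np

import rocshape as rs


def brute_force_auroc(values, labels, direction=rs.Direction.HIGHER_PREDICTS_EVENT):
    """Exact pairwise AUROC: mean over all case-control pairs of
    1 / 0.5 / 0 for win / tie / loss."""
    v = np.asarray(values, dtype=float)
    if direction is rs.Direction.LOWER_PREDICTS_EVENT:
        v = -v
    y = np.asarray(labels)
    pos = v[y == 1]
    neg = v[y == 0]
    total = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                total += 1
            elif p == q:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


def random_tied_sample(rng, n_min=2, n_max=50):
    """A small random sample with heavy ties and both classes present."""
    n = int(rng.integers(n_min, n_max + 1))
    values = rng.integers(0, 6, size=n).astype(float)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[rng.integers(0, n)] = 1 - labels[0]
    return rs.BinaryOutcomeSample(values, labels)
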