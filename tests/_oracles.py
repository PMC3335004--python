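"""Independent brute-force oracles shared by the statistical tests."""

import math

import numpy as np


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration over all
    tables with the observed margins (point-probability rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):  # x = top-left cell
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    p_obs = table_prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(
        table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= p_obs * (1 + 1e-9)
    )


def auroc_pairwise_oracle(values, labels):
    """Mann-Whitney probability by brute-force pairwise counting."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    cases, controls = v[y], v[~y]
    wins = 0.0
    for x in cases:
        for z in controls:
            wins += 1.0 if x > z else (0.5 if x == z else 0.0)
    return wins / (len(cases) * len(controls))
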