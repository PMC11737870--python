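"""Shared independent oracles for the test suite."""

import numpy as np


def bh_stepup_reference(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
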