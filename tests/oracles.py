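"""Independent brute-force oracles shared by the unit and acceptance tests.

These deliberately avoid the production code paths (and sklearn): plain
loops over enumerated neighbors and frequency bins.
"""

import numpy as np


def eq9_oracle(X_train, y_train, x_new, k=5, weight_mode="inverse_prior",
               positive="independent"):
    """Distance-weighted KNN posterior of the positive class by explicit
    neighbor enumeration and term-by-term weight evaluation."""
    d = np.array([np.sqrt(np.sum((x - x_new) ** 2)) for x in X_train])
    order = np.argsort(d, kind="stable")[:k]
    y = np.asarray(y_train)
    priors = {c: np.mean(y == c) for c in np.unique(y)}
    if np.any(d[order] == 0):
        zero = [i for i in order if d[i] == 0]
        return float(np.mean([y[i] == positive for i in zero]))
    num = den = 0.0
    for i in order:
        w = (1.0 / d[i]) / priors[y[i]]
        if weight_mode == "raw_distance":
            w = d[i] / priors[y[i]]
        num += w * (y[i] == positive)
        den += w
    return num / den


def imnf_oracle(freqs, p):
    """Weighted-mean frequency of one frame, accumulated term by term."""
    num = 0.0
    den = 0.0
    for f, pw in zip(freqs, p):
        num += f * pw
        den += pw
    return num / den


def imdf_oracle(freqs, p):
    """Smallest grid frequency where cumulative power reaches half the
    total, found by exhaustive scan (the discrete median convention)."""
    total = sum(p)
    c = 0.0
    for f, pw in zip(freqs, p):
        c += pw
        if c >= total / 2.0:
            return f
    return freqs[-1]
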