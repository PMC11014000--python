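"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized cascade: filtering is
done by explicit per-index loops with index-wise circular wrap-around,
and the fitness statistics are recomputed coefficient by coefficient.
"""

import math

import numpy as np


def circular_downsample_filter(x, filt):
    """y[n] = sum_k filt[k] * x[(2n + L//2 - k) mod N], explicit loops."""
    n = len(x)
    length = len(filt)
    out = []
    for i in range(n // 2):
        acc = 0.0
        for k in range(length):
            acc += filt[k] * x[(2 * i + length // 2 - k) % n]
        out.append(acc)
    return np.array(out)


def naive_wpt(signal, dec_lo, dec_hi, level):
    """Full packet cascade by naive convolution; natural node order."""
    x = list(np.asarray(signal, dtype=float))
    block = 2 ** level
    padded = math.ceil(len(x) / block) * block
    x = np.array(x + [0.0] * (padded - len(x)))
    nodes = [x]
    for _ in range(level):
        nxt = []
        for node in nodes:
            nxt.append(circular_downsample_filter(node, dec_lo))
            nxt.append(circular_downsample_filter(node, dec_hi))
        nodes = nxt
    return nodes


def naive_fitness(coefficients, log=math.log):
    """(energy, entropy, ratio) computed term by term from pooled coeffs."""
    coeffs = [float(c) for c in coefficients]
    energy = sum(c * c for c in coeffs)
    entropy = 0.0
    for c in coeffs:
        p = c * c / energy
        if p > 0.0:
            entropy -= p * log(p)
    return energy, entropy, energy / entropy
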