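"""Independent brute-force oracles, coded directly from the definitions.

Deliberately written with plain Python loops and ``math`` (no numpy
vectorization, no calls into the package) so they constitute a separate
computational path from the implementation they check.
"""

import cmath
import math


def time_domain_oracle(s):
    """The 14 time-domain statistics, one term at a time."""
    s = list(map(float, s))
    n = len(s)
    mean = sum(s) / n
    var = sum((x - mean) ** 2 for x in s) / (n - 1)
    sd = math.sqrt(var)
    smax, smin = max(s), min(s)
    power = sum(x * x for x in s) / n
    rms = math.sqrt(power)
    skew = (sum((x - mean) ** 3 for x in s) / n) / sd**3
    kurt = (sum((x - mean) ** 4 for x in s) / n) / sd**4
    margin = smax / (sum(math.sqrt(abs(x)) for x in s) / n) ** 2
    return {
        "s_mean": mean,
        "s_var": var,
        "s_sd": sd,
        "s_max": smax,
        "s_min": smin,
        "s_p2p": smax - smin,
        "s_rms": rms,
        "s_power": power,
        "s_crest": smax / rms,
        "s_skew": skew,
        "s_kurt": kurt,
        "s_form": rms / mean,
        "s_pulse": smax / mean,
        "s_margin": margin,
    }


def dft_oracle(s):
    """Naive O(n^2) two-sided DFT."""
    n = len(s)
    return [
        sum(s[t] * cmath.exp(-2j * cmath.pi * k * t / n) for t in range(n))
        for k in range(n)
    ]


def band_power_oracle(s):
    """One-sided periodogram from the naive DFT, DC included."""
    full = dft_oracle(list(map(float, s)))
    return [abs(z) ** 2 for z in full[: len(s) // 2 + 1]]


def frequency_domain_oracle(f):
    """The 8 band-power-spectrum statistics, one term at a time."""
    f = list(map(float, f))
    m = len(f)
    mean = sum(f) / m
    var = sum((x - mean) ** 2 for x in f) / (m - 1)
    return {
        "f_mean": mean,
        "f_var": var,
        "f_sd": math.sqrt(var),
        "f_max": max(f),
        "f_sum": sum(f),
        "f_skew": (sum((x - mean) ** 3 for x in f) / m) / var**1.5,
        "f_kurt": (sum((x - mean) ** 4 for x in f) / m) / var**2,
        "f_rsp": max(f) / mean,
    }


def mann_whitney_auc_oracle(scores, labels):
    """Tie-corrected pairwise concordance over all positive x negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels):
    """Exhaustive scan of J = TPR - FPR over unique scores plus +inf.

    Decision rule: predict positive iff score >= threshold; ties on J break
    to the smallest threshold.
    """
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    best_j, best_t = -2.0, None
    for t in sorted(set(scores)) + [math.inf]:
        tpr = sum(1 for s in pos if s >= t) / len(pos)
        fpr = sum(1 for s in neg if s >= t) / len(neg)
        j = tpr - fpr
        if j > best_j or (j == best_j and (best_t is None or t < best_t)):
            best_j, best_t = j, t
    return best_t, best_j


def a20_oracle(scores, labels):
    """Direct count of confidently correct predictions, boundaries inclusive."""
    m20 = sum(
        1
        for s, y in zip(scores, labels)
        if (y == 0 and s <= 0.2) or (y == 1 and s >= 0.8)
    )
    return m20 / len(scores)
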