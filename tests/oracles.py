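"""Independent brute-force oracles for the test statistics.

Plain-Python loop implementations of the defining formulas, kept free of
the package's vectorised code paths so that agreement is evidence, not
tautology.
"""

import math

TWO_PI = 2.0 * math.pi


def spacings_brute(angles):
    s = sorted(angles)
    n = len(s)
    t = [s[i + 1] - s[i] for i in range(n - 1)]
    t.append(TWO_PI - s[-1] + s[0])
    return t


def rao_brute(angles):
    n = len(angles)
    return 0.5 * sum(abs(t - TWO_PI / n) for t in spacings_brute(angles))


def gini_brute(angles):
    t = spacings_brute(angles)
    n = len(t)
    acc = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            acc += 0.5 * abs(n * t[i] - n * t[j])
    return 2.0 * acc / (n * (n - 1))


def hr_brute(angles):
    n = len(angles)
    acc = 0.0
    for a in angles:
        for b in angles:
            d = a - b
            acc += abs(abs(d) - math.pi) - math.pi / 2 - 2.895 * (abs(math.sin(d)) - 2 / math.pi)
    return acc / n


def kuiper_brute(angles):
    n = len(angles)
    u = sorted(a / TWO_PI for a in angles)
    dplus = max((i + 1) / n - u[i] for i in range(n))
    dminus = max(u[i] - i / n for i in range(n))
    return math.sqrt(n) * (dplus + dminus)


def watson_brute(angles):
    n = len(angles)
    u = sorted(a / TWO_PI for a in angles)
    ubar = sum(u) / n
    acc = sum((u[i] - (2 * (i + 1) - 1) / (2 * n)) ** 2 for i in range(n))
    return acc - n * (ubar - 0.5) ** 2 + 1 / (12 * n)


def chisq_brute(counts, n):
    m = len(counts)
    e = n / m
    return sum((o - e) ** 2 / e for o in counts)
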