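"""Independent brute-force oracles used by the test suite.

Everything here is coded directly from the stated definitions with plain
Python loops (or a direct normal-equations solve), independently of the
vectorised implementations in the package.
"""

import math

import numpy as np

EPS = 1e-12


# --- scalar window features -------------------------------------------------

def mav(x):
    return sum(abs(v) for v in x) / len(x)


def iemg(x):
    return sum(abs(v) for v in x)


def rms(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def var(x):
    m = sum(x) / len(x)
    return sum((v - m) ** 2 for v in x) / (len(x) - 1)


def wl(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def dasdv(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return math.sqrt(sum(v * v for v in d) / len(d))


def mavfd(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    return sum(abs(v) for v in d) / len(d)


def mfl(x):
    s = math.sqrt(sum((x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)))
    return math.log10(max(s, EPS))


def msr(x):
    return sum(math.sqrt(abs(v)) for v in x) / len(x)


def ls(x):
    """L-scale: second L-moment of the sorted sample."""
    xs = sorted(x)
    n = len(xs)
    b0 = sum(xs) / n
    b1 = sum(i * xs[i] for i in range(n)) / (n * (n - 1))
    return 2 * b1 - b0


def zc(x, threshold=0.0):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) > threshold:
            count += 1
    return count


def ssc(x, threshold=0.0):
    count = 0
    for i in range(1, len(x) - 1):
        d1 = x[i] - x[i - 1]
        d2 = x[i] - x[i + 1]
        if d1 * d2 > 0 and max(abs(d1), abs(d2)) > threshold:
            count += 1
    return count


def wamp(x, threshold=0.02):
    return sum(1 for i in range(len(x) - 1) if abs(x[i] - x[i + 1]) > threshold)


def act(x):
    m = sum(x) / len(x)
    return sum((v - m) ** 2 for v in x) / len(x)


def mob(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    v0, v1 = act(x), act(d)
    return math.sqrt(v1 / v0) if v0 > 0 else 0.0


def comp(x):
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    m0 = mob(x)
    return mob(d) / m0 if m0 > 0 else 0.0


def ar4(x, order=4):
    """Yule-Walker by direct normal equations on the biased autocovariance of
    the demeaned window."""
    n = len(x)
    m = sum(x) / n
    y = [v - m for v in x]
    r = [sum(y[i] * y[i + k] for i in range(n - k)) / n for k in range(order + 1)]
    if r[0] <= 0:
        return [0.0] * order
    big_r = [[r[abs(i - j)] for j in range(order)] for i in range(order)]
    return list(np.linalg.solve(np.array(big_r), np.array(r[1 : order + 1])))


def sampen(x, m=2, r_factor=0.2):
    """Sample entropy, m-template count matched to the m+1 count (N - m
    templates each), Chebyshev distance, tolerance '<= r', self-matches
    excluded; undefined cases mirror the package's documented fallbacks."""
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def count(mm):
        total = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                d = max(abs(x[i + t] - x[j + t]) for t in range(mm))
                if d <= r:
                    total += 1
        return total

    b = count(m)
    if b <= 0:
        return 0.0
    a = max(count(m + 1), 1)
    return -math.log(a / b)


def tdpsd(x, fused=True):
    """Direct transcription of the six-descriptor construction."""

    def descriptors(sig):
        d1 = [sig[i + 1] - sig[i] for i in range(len(sig) - 1)]
        d2 = [d1[i + 1] - d1[i] for i in range(len(d1) - 1)]
        m0 = math.sqrt(sum(v * v for v in sig))
        m2 = math.sqrt(sum(v * v for v in d1))
        m4 = math.sqrt(sum(v * v for v in d2))
        m0, m2, m4 = (max(m, EPS) ** 0.1 / 0.1 for m in (m0, m2, m4))

        def logc(v):
            return math.log(max(abs(v), EPS))

        a = [
            logc(m0),
            logc(m0 - m2),
            logc(m0 - m4),
            logc(m0 / math.sqrt(max(abs((m0 - m2) * (m0 - m4)), EPS))),
            logc(m2 / math.sqrt(max(m0 * m4, EPS))),
            logc(sum(abs(v) for v in d1) / max(sum(abs(v) for v in d2), EPS)),
        ]
        return a

    a = descriptors(list(x))
    if not fused:
        return a
    b = descriptors([math.log(v * v + EPS) for v in x])
    out = []
    for ai, bi in zip(a, b):
        denom = ai * ai + bi * bi
        out.append(-2 * ai * bi / denom if denom > 0 else 0.0)
    return out


# --- evaluation metrics -----------------------------------------------------

def ter(p, l):
    wrong = sum(1 for a, b in zip(p, l) if a != b)
    return 100.0 * wrong / len(p)


def aer(p, l, nm):
    num = sum(1 for a, b in zip(p, l) if a != b and a != nm)
    den = sum(1 for a in p if a != nm)
    if den == 0:
        return None
    return 100.0 * num / den


def dbi(x, labels):
    """Davies-Bouldin with mean-squared dispersion and squared Euclidean
    separation, averaging each cluster's worst overlap."""
    x = [list(map(float, row)) for row in x]
    classes = sorted(set(labels))
    mus, ss = [], []
    for c in classes:
        rows = [x[i] for i in range(len(x)) if labels[i] == c]
        mu = [sum(col) / len(rows) for col in zip(*rows)]
        s = sum(sum((v - m) ** 2 for v, m in zip(row, mu)) for row in rows) / len(rows)
        mus.append(mu)
        ss.append(s)
    worst = []
    for i in range(len(classes)):
        best = -math.inf
        for j in range(len(classes)):
            if i == j:
                continue
            d = sum((a - b) ** 2 for a, b in zip(mus[i], mus[j]))
            r = math.inf if d == 0 else (ss[i] + ss[j]) / d
            best = max(best, r)
        worst.append(best)
    return sum(worst) / len(worst)


# --- segmentation -----------------------------------------------------------

def window_count(n_samples, length, inc):
    """Enumerate valid start indices directly."""
    count = 0
    start = 0
    while start + length <= n_samples:
        count += 1
        start += inc
    return count
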