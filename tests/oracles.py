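"""Independent literal-equation reference implementations.

These deliberately mirror the step-by-step definitions of DFA and the
Higuchi fractal dimension with plain Python loops; the package's vectorised
code is tested against them, never the other way round.
"""

import numpy as np


def dfa_literal(x, box_sizes):
    """Step-by-step DFA: integrate, per-box linear detrend, RMS residual,
    log-log slope."""
    x = np.asarray(x, float)
    N = len(x)
    y = np.cumsum(x - np.mean(x))
    Fs = []
    for n in box_sizes:
        nb = N // n
        sq_sum = 0.0
        count = 0
        for b in range(nb):
            seg = y[b * n:(b + 1) * n]
            t = np.arange(n, dtype=float)
            slope, intercept = np.polyfit(t, seg, 1)
            resid = seg - (slope * t + intercept)
            sq_sum += float(np.sum(resid ** 2))
            count += n
        Fs.append(np.sqrt(sq_sum / count))
    alpha = np.polyfit(np.log(box_sizes), np.log(Fs), 1)[0]
    return float(alpha), np.array(Fs)


def higuchi_literal(x, k_max):
    """Triple-loop Higuchi curve lengths and dimension."""
    x = np.asarray(x, float)
    N = len(x)
    Ls = []
    for k in range(1, k_max + 1):
        Lm_values = []
        for m in range(1, k + 1):
            M = (N - m) // k
            dist = 0.0
            for i in range(1, M + 1):
                dist += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
            Lm_values.append(dist * (N - 1) / (M * k) / k)
        Ls.append(np.mean(Lm_values))
    dim = -np.polyfit(np.log(np.arange(1, k_max + 1)), np.log(Ls), 1)[0]
    return float(dim), np.array(Ls)


def periodogram_entropy(x, fs):
    """Direct-periodogram spectral entropy (coarse oracle for the Welch
    estimate: agrees on flat-vs-peaky ordering, not to high precision)."""
    x = np.asarray(x, float)
    P = np.abs(np.fft.rfft(x)) ** 2
    P = P[1:]
    p = P / P.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(len(P)))
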