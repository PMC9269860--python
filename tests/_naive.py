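"""Independent naive reference implementations used as oracles.

Everything here is written with explicit Python loops over the printed
single-window definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import cmath
import math


def naive_mav(x):
    return sum(abs(v) for v in x) / len(x)


def naive_var(x):
    return sum(v * v for v in x) / (len(x) - 1)


def naive_ssc(x, thr):
    n = len(x)
    c = 0
    for i in range(1, n - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= thr:
            c += 1
    return c


def naive_zc(x, thr):
    c = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= thr:
            c += 1
    return c


def naive_wa(x, thr):
    c = 0
    for i in range(len(x) - 1):
        if abs(x[i] - x[i + 1]) >= thr:
            c += 1
    return c


def naive_wl(x):
    return sum(abs(x[i] - x[i + 1]) for i in range(len(x) - 1))


def naive_env(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def naive_spectrum(x, fs):
    """One-sided |DFT|^2 with f_n = n * fs / N, computed by direct summation."""
    n = len(x)
    m = n // 2 + 1
    P, f = [], []
    for k in range(m):
        acc = 0j
        for j, v in enumerate(x):
            acc += v * cmath.exp(-2j * math.pi * k * j / n)
        P.append(abs(acc) ** 2)
        f.append(k * fs / n)
    return P, f


def naive_etot(P):
    m = len(P)
    return sum(P[: m - 1]) / (m - 1)


def naive_tf(P, f):
    m = len(P)
    return sum(P[i] * f[i] ** 2 for i in range(m - 1))


def naive_tf_mod(P, f):
    m = len(P)
    return sum(P[i] * f[i] for i in range(m - 1))


def naive_mnf(P, f):
    return sum(p * fi for p, fi in zip(P, f)) / sum(P)


def naive_mdf(P, f):
    total = sum(P)
    acc = 0.0
    for p, fi in zip(P, f):
        acc += p
        if acc >= 0.5 * total:
            return fi
    return f[-1]


def naive_teager(x):
    """Pointwise psi for interior samples (index j is center j+1)."""
    return [x[i] ** 2 - x[i - 1] * x[i + 1] for i in range(1, len(x) - 1)]


def naive_ttd_window(x_signal, i, n):
    """Causal smoothed Ttd at newest sample i: mean of psi over centers
    i-n .. i-1, clipped to the first available center (1)."""
    lo = max(1, i - n)
    hi = i - 1
    vals = [
        x_signal[c] ** 2 - x_signal[c - 1] * x_signal[c + 1] for c in range(lo, hi + 1)
    ]
    return sum(vals) / len(vals)


def naive_fr_window(x, thr, dead):
    """Rising crossings of |x| above thr (predecessor inside the window),
    greedy dead-time suppression restarting at the window start."""
    above = [abs(v) > thr for v in x]
    count = 0
    last = None
    for i in range(1, len(x)):
        if above[i] and not above[i - 1]:
            if last is None or i >= last + dead:
                count += 1
                last = i
    return count


def naive_window_value(algorithm, x, fs, thr=0.0, dead=50):
    """Dispatch a single-window evaluation by acronym."""
    if algorithm == "MAV":
        return naive_mav(x)
    if algorithm == "Var":
        return naive_var(x)
    if algorithm == "SSC":
        return naive_ssc(x, thr)
    if algorithm == "ZC":
        return naive_zc(x, thr)
    if algorithm == "WA":
        return naive_wa(x, thr)
    if algorithm == "WL":
        return naive_wl(x)
    if algorithm == "Env":
        return naive_env(x)
    if algorithm == "FR":
        return naive_fr_window(x, thr, dead)
    P, f = naive_spectrum(x, fs)
    if algorithm == "Etot":
        return naive_etot(P)
    if algorithm == "Tf":
        return naive_tf(P, f)
    if algorithm == "Tf_mod":
        return naive_tf_mod(P, f)
    if algorithm == "MNF":
        return naive_mnf(P, f)
    if algorithm == "MDF":
        return naive_mdf(P, f)
    raise ValueError(algorithm)
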