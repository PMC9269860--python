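"""The fourteen sliding-window iEMG feature operators.

Each operator is defined on one analysis window of ``N`` consecutive filtered
iEMG samples and lifted to a causal sliding-window series by
:func:`sliding_apply`: the value computed on samples ``i-N+1 .. i`` is
adjoined to the newest sample ``i``, so every output depends only on past and
present samples.

Acronyms (fixed set): MAV, Var, SSC, ZC, WA, WL, Env, Etot, Ttd, Tf, Tf_mod,
MNF, MDF, FR.

Conventions
-----------
* ``Var`` uses the zero-mean simplification ``sum(x^2)/(N-1)`` (the iEMG mean
  is ~0; no mean subtraction).
* Count features (SSC, ZC, WA) are gated by an amplitude dead zone derived
  from the resting-noise MAV; the SSC dead zone is squared because the SSC
  indicator acts on a product of slopes (uV^2).
* Spectral features use the one-sided magnitude-squared DFT of the raw
  (rectangular, unpadded) window; the DC band is included in the MNF/MDF
  sums, and Etot/Tf/Tf_mod sum bands 1..M-1 (the last band is excluded).
* FR counts action-potential events: rising crossings of ``|x|`` above a
  quantile threshold, with subsequent crossings ignored for a dead time
  (default 5 ms, a typical MUAP duration).
* The pointwise Teager-Kaiser energy ``psi_n = x_n^2 - x_{n-1} x_{n+1}``
  needs one future sample, so the causal Ttd series at newest sample ``i``
  averages the ``N`` most recent fully available ``psi`` values (centers
  ``i-N .. i-1``, clipped at the start of the signal).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

ALGORITHMS = (
    "MAV", "Var", "SSC", "ZC", "WA", "WL", "Env",
    "Etot", "Ttd", "Tf", "Tf_mod", "MNF", "MDF", "FR",
)
TIME_DOMAIN = ("MAV", "Var", "WL", "Env")
THRESHOLDED = ("SSC", "ZC", "WA")
SPECTRAL = ("Etot", "Tf", "Tf_mod", "MNF", "MDF")

_CHUNK = 512  # windows gathered per vectorized batch


# ---------------------------------------------------------------------------
# window / threshold specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width in ms and evaluation hop in samples."""

    width_ms: float
    sampling_rate: float = 10_000.0
    increment_samples: int = 100  # 10 ms at 10 kHz

    def __post_init__(self) -> None:
        if self.width_samples < 3:
            raise ValueError("window must hold >= 3 samples")
        if self.increment_samples < 1:
            raise ValueError("increment_samples must be >= 1")

    @property
    def width_samples(self) -> int:
        return int(round(self.width_ms * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class ThresholdSpec:
    """Dead-zone (Q x resting MAV) or quantile-based amplitude threshold.

    ``resolve`` binds the spec to a segment: the dead zone needs the rest
    MAV, the quantile needs the iEMG over the first full tracking period.
    """

    kind: str  # 'dead_zone' | 'quantile'
    q_multiplier: float | None = None
    quantile: float | None = None
    dead_time_ms: float = 5.0
    resolved_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "dead_zone":
            if self.q_multiplier is None or self.q_multiplier < 0:
                raise ValueError("dead_zone threshold needs q_multiplier >= 0")
        elif self.kind == "quantile":
            if self.quantile is None or not 85 <= self.quantile <= 99:
                raise ValueError("quantile threshold must lie in [85, 99]")
        else:
            raise ValueError(f"unknown threshold kind: {self.kind!r}")

    def resolve(self, algorithm: str, rest_mav: float | None = None,
                reference_signal: np.ndarray | None = None) -> "ThresholdSpec":
        if self.kind == "dead_zone":
            if rest_mav is None:
                raise ValueError("dead_zone threshold needs the rest MAV")
            v = self.q_multiplier * float(rest_mav)
            if algorithm == "SSC":  # indicator acts on a slope product (uV^2)
                v = v * v
        else:
            if reference_signal is None:
                raise ValueError("quantile threshold needs a reference signal")
            v = float(np.percentile(np.abs(np.asarray(reference_signal, float)), self.quantile))
        return dataclasses.replace(self, resolved_value=v)


def _resolved(threshold) -> float:
    if threshold is None:
        return 0.0
    if isinstance(threshold, ThresholdSpec):
        if threshold.resolved_value is None:
            raise ValueError("threshold spec is not resolved; call .resolve() first")
        return float(threshold.resolved_value)
    return float(threshold)


# ---------------------------------------------------------------------------
# single-window operators
# ---------------------------------------------------------------------------


def mav(x) -> float:
    """Mean absolute value, uV."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def var(x) -> float:
    """Zero-mean variance ``sum(x^2)/(N-1)``, uV^2."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("Var needs N >= 2")
    return float(np.sum(x * x) / (x.size - 1))


def ssc(x, threshold=0.0) -> int:
    """Slope-sign-change count with a dead zone on the slope product."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("SSC needs N >= 3")
    thr = _resolved(threshold)
    p = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return int(np.count_nonzero(p >= thr))


def zc(x, threshold=0.0) -> int:
    """Zero-crossing count gated by an amplitude dead zone."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("ZC needs N >= 2")
    thr = _resolved(threshold)
    sign_change = x[:-1] * x[1:] < 0
    big = np.abs(x[:-1] - x[1:]) >= thr
    return int(np.count_nonzero(sign_change & big))


def wa(x, threshold=0.0) -> int:
    """Willison amplitude: consecutive differences exceeding the threshold."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("WA needs N >= 2")
    thr = _resolved(threshold)
    return int(np.count_nonzero(np.abs(x[:-1] - x[1:]) >= thr))


def wl(x) -> float:
    """Waveform length: cumulative absolute sample-to-sample excursion, uV."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("WL needs N >= 2")
    return float(np.sum(np.abs(np.diff(x))))


def env(x) -> float:
    """Signal envelope: root mean square over the window, uV."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x * x)))


# ---------------------------------------------------------------------------
# spectrum and spectral operators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided magnitude-squared DFT spectrum of one window.

    ``P[n] = |X[n]|^2`` for the rectangular, unpadded window;
    ``f[n] = n * fs / N``.  Parseval under this convention:
    ``sum(x^2) = (P[0] + 2*sum(P[1:-1]) + c*P[-1]) / N`` with ``c = 1`` for
    even N (Nyquist bin) and ``c = 2`` for odd N.
    """

    P: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.P < 0):
            raise ValueError("spectral power must be non-negative")
        if np.any(np.diff(self.f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def M(self) -> int:
        return self.P.size


def power_spectrum(x, sampling_rate: float) -> PowerSpectrum:
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("spectrum needs N >= 4")
    F = np.fft.rfft(x)
    P = np.abs(F) ** 2
    f = np.arange(P.size) * (sampling_rate / x.size)
    return PowerSpectrum(P=P, f=f)


def etot(ps: PowerSpectrum) -> float:
    """Total signal energy: mean of spectral powers over bands 1..M-1."""
    if ps.M < 2:
        raise ValueError("Etot needs M >= 2")
    return float(np.sum(ps.P[: ps.M - 1]) / (ps.M - 1))


def tf(ps: PowerSpectrum) -> float:
    """Teager energy in the frequency domain: sum P_n * f_n^2 over 1..M-1."""
    if ps.M < 2:
        raise ValueError("Tf needs M >= 2")
    return float(np.sum(ps.P[: ps.M - 1] * ps.f[: ps.M - 1] ** 2))


def tf_mod(ps: PowerSpectrum) -> float:
    """Modified Teager energy: sum P_n * f_n over 1..M-1 (no squaring)."""
    if ps.M < 2:
        raise ValueError("Tf_mod needs M >= 2")
    return float(np.sum(ps.P[: ps.M - 1] * ps.f[: ps.M - 1]))


def mnf(ps: PowerSpectrum) -> float:
    """Mean (power-weighted average) frequency, Hz."""
    total = float(np.sum(ps.P))
    if total <= 0:
        raise ValueError("MNF undefined for an all-zero spectrum")
    return float(np.sum(ps.P * ps.f) / total)


def mdf(ps: PowerSpectrum) -> float:
    """Median frequency: smallest f_k whose cumulative power reaches half."""
    total = float(np.sum(ps.P))
    if total <= 0:
        raise ValueError("MDF undefined for an all-zero spectrum")
    cs = np.cumsum(ps.P)
    k = int(np.searchsorted(cs, 0.5 * total))
    return float(ps.f[k])


# ---------------------------------------------------------------------------
# Teager-Kaiser and FR
# ---------------------------------------------------------------------------


def teager_kaiser(x) -> np.ndarray:
    """Pointwise Teager-Kaiser energy ``psi_n = x_n^2 - x_{n-1} x_{n+1}`` for
    interior samples; element ``j`` corresponds to center sample ``j+1``."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Teager-Kaiser needs >= 3 samples")
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def fr(x, threshold, sampling_rate: float, dead_time_ms: float = 5.0) -> int:
    """Firing rate on one window: rising crossings of ``|x|`` above the
    threshold, with crossings during the dead time after an accepted event
    ignored.  A rising crossing needs its predecessor inside the window."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("FR needs N >= 2")
    thr = _resolved(threshold)
    if thr <= 0:
        raise ValueError("FR threshold must be positive")
    above = np.abs(x) > thr
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    dead = max(1, int(round(dead_time_ms * sampling_rate / 1000.0)))
    count = 0
    last = -np.inf
    for e in edges:
        if e >= last + dead:
            count += 1
            last = e
    return count


# ---------------------------------------------------------------------------
# sliding-window series
# ---------------------------------------------------------------------------


@dataclass
class FeatureSeries:
    """Causal feature series: ``values[i]`` is the operator applied to the
    window ending at ``sample_index[i]`` (the newest window sample)."""

    values: np.ndarray
    sample_index: np.ndarray
    algorithm: str
    window: WindowSpec
    threshold: ThresholdSpec | float | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"sample_index": self.sample_index, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _eval_indices(n: int, window: WindowSpec) -> np.ndarray:
    N = window.width_samples
    if n < N:
        raise ValueError("signal shorter than the analysis window")
    return np.arange(N - 1, n, window.increment_samples, dtype=np.int64)


def _gathered(x: np.ndarray, idx: np.ndarray, N: int):
    """Yield (row_slice, window_matrix) chunks of gathered windows."""
    view = np.lib.stride_tricks.sliding_window_view(x, N)
    for a in range(0, idx.size, _CHUNK):
        rows = idx[a : a + _CHUNK] - N + 1
        yield slice(a, a + rows.size), view[rows]


def _sliding_time_domain(x, idx, N, algorithm):
    out = np.empty(idx.size, dtype=float)
    for sl, W in _gathered(x, idx, N):
        if algorithm == "MAV":
            out[sl] = np.mean(np.abs(W), axis=1)
        elif algorithm == "Var":
            out[sl] = np.sum(W * W, axis=1) / (N - 1)
        elif algorithm == "Env":
            out[sl] = np.sqrt(np.mean(W * W, axis=1))
        elif algorithm == "WL":
            out[sl] = np.sum(np.abs(np.diff(W, axis=1)), axis=1)
    return out


def _sliding_counts(x, idx, N, algorithm, thr):
    # windowed sums of global pointwise indicators via exact integer cumsums
    if algorithm == "SSC":
        p = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
        ind = (p >= thr).astype(np.int64)
        c = np.concatenate([[0], np.cumsum(ind)])
        # centers at global positions (i-N+2 .. i-1); ind[j] is center j+1
        return (c[idx - 1] - c[idx - N + 1]).astype(float)
    d = np.abs(x[:-1] - x[1:])
    if algorithm == "ZC":
        ind = ((x[:-1] * x[1:] < 0) & (d >= thr)).astype(np.int64)
    else:  # WA
        ind = (d >= thr).astype(np.int64)
    c = np.concatenate([[0], np.cumsum(ind)])
    # pairs at global positions (i-N+1 .. i-1)
    return (c[idx] - c[idx - N + 1]).astype(float)


def _sliding_spectral(x, idx, N, sampling_rate, names):
    M = N // 2 + 1
    f = np.arange(M) * (sampling_rate / N)
    out = {name: np.empty(idx.size, dtype=float) for name in names}
    for sl, W in _gathered(x, idx, N):
        P = np.abs(np.fft.rfft(W, axis=1)) ** 2
        total = P.sum(axis=1)
        for name in names:
            if name == "Etot":
                out[name][sl] = P[:, : M - 1].sum(axis=1) / (M - 1)
            elif name == "Tf":
                out[name][sl] = P[:, : M - 1] @ (f[: M - 1] ** 2)
            elif name == "Tf_mod":
                out[name][sl] = P[:, : M - 1] @ f[: M - 1]
            elif name == "MNF":
                if np.any(total <= 0):
                    raise ValueError("MNF undefined for an all-zero window")
                out[name][sl] = (P @ f) / total
            elif name == "MDF":
                if np.any(total <= 0):
                    raise ValueError("MDF undefined for an all-zero window")
                cs = np.cumsum(P, axis=1)
                k = np.argmax(cs >= 0.5 * total[:, None], axis=1)
                out[name][sl] = f[k]
    return out


def _sliding_ttd(x, idx, N):
    psi = teager_kaiser(x)  # psi[j] <-> center j+1
    c = np.concatenate([[0.0], np.cumsum(psi)])
    lo = np.maximum(1, idx - N)  # first usable center
    hi = idx - 1  # newest fully available center
    sums = c[hi] - c[lo - 1]  # psi index of center m is m-1
    counts = hi - lo + 1
    return sums / counts


def _sliding_fr(x, idx, N, thr, dead):
    """Per-window FR counts via a binary-lifting successor chain.

    Global rising edges of ``|x| > thr`` are chained by "first edge at least
    ``dead`` samples later"; the greedy per-window count (restarting at each
    window start) is the chain-path length inside the window.
    """
    above = np.abs(x) > thr
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    counts = np.zeros(idx.size, dtype=float)
    if edges.size == 0:
        return counts
    E = edges.size
    nxt = np.searchsorted(edges, edges + dead)
    levels = [np.concatenate([nxt, [E]])]
    max_count = N // max(dead, 1) + 2
    while (1 << len(levels)) <= max_count:
        prev = levels[-1]
        levels.append(prev[np.minimum(prev, E)])
    starts = idx - N + 1
    cur = np.searchsorted(edges, starts + 1)  # first edge with in-window predecessor
    padded = np.concatenate([edges, [np.iinfo(np.int64).max]])
    active = padded[np.minimum(cur, E)] <= idx
    counts[active] = 1.0
    cur = np.where(active, cur, E)
    for k in range(len(levels) - 1, -1, -1):
        j = levels[k][np.minimum(cur, E)]
        ok = active & (padded[np.minimum(j, E)] <= idx)
        counts[ok] += float(1 << k)
        cur = np.where(ok, j, cur)
    return counts


def ttd(x, window: WindowSpec) -> FeatureSeries:
    """Teager energy in the time domain: pointwise Teager-Kaiser values
    smoothed by a causal moving average of the window width."""
    x = np.asarray(x, dtype=float)
    idx = _eval_indices(x.size, window)
    return FeatureSeries(_sliding_ttd(x, idx, window.width_samples), idx, "Ttd", window)


def sliding_apply(
    x,
    algorithm: str,
    window: WindowSpec,
    threshold: ThresholdSpec | float | None = None,
) -> FeatureSeries:
    """Evaluate one operator on every sliding-window hop.

    The output value at evaluation instant ``i`` equals the operator applied
    to samples ``i-N+1 .. i``; the first output sits at the ``N``-th sample.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm acronym: {algorithm!r}")
    x = np.asarray(x, dtype=float)
    N = window.width_samples
    idx = _eval_indices(x.size, window)
    if algorithm in TIME_DOMAIN:
        values = _sliding_time_domain(x, idx, N, algorithm)
    elif algorithm in THRESHOLDED:
        values = _sliding_counts(x, idx, N, algorithm, _resolved(threshold))
    elif algorithm in SPECTRAL:
        values = _sliding_spectral(x, idx, N, window.sampling_rate, [algorithm])[algorithm]
    elif algorithm == "Ttd":
        values = _sliding_ttd(x, idx, N)
    else:  # FR
        thr = _resolved(threshold)
        if thr <= 0:
            raise ValueError("FR threshold must be positive")
        dead_ms = threshold.dead_time_ms if isinstance(threshold, ThresholdSpec) else 5.0
        dead = max(1, int(round(dead_ms * window.sampling_rate / 1000.0)))
        values = _sliding_fr(x, idx, N, thr, dead)
    return FeatureSeries(values, idx, algorithm, window, threshold)


def sliding_spectral_set(x, window: WindowSpec, names=SPECTRAL) -> dict[str, FeatureSeries]:
    """All requested spectral feature series from a single FFT pass per hop."""
    x = np.asarray(x, dtype=float)
    idx = _eval_indices(x.size, window)
    vals = _sliding_spectral(x, idx, window.width_samples, window.sampling_rate, list(names))
    return {name: FeatureSeries(v, idx, name, window) for name, v in vals.items()}
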