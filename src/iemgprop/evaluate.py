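"""Metrics, the brute-force parameter sweep, aggregation and statistics.

Metrics: RMSE between normalized measured and estimated force (in percent,
no time-lag compensation) and the zero-lag Pearson correlation.  The sweep
evaluates every algorithm on every grid point (window widths 50-1050 ms in
100 ms steps, shortened to 50-550 ms for the dead-zone algorithms; dead-zone
multipliers Q = 0..4 step 0.2; FR quantiles 85..99) for every segment, with
per-cell failures recorded rather than fatal.

Statistics: Lilliefors normality test, Friedman omnibus test on within-block
ranks, and a Dunn-type Bonferroni-corrected pairwise comparison of mean
ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import control, features, preprocess


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def rmse_percent(measured, estimated) -> float:
    """100 x root-mean-square sample-to-sample error, no lag alignment."""
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ValueError("measured and estimated traces differ in length")
    d = m - e
    return float(100.0 * np.sqrt(np.mean(d * d)))


def zero_lag_pearson(measured, estimated) -> float:
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ValueError("measured and estimated traces differ in length")
    if np.ptp(m) == 0 or np.ptp(e) == 0:
        raise ValueError("Pearson correlation undefined for a constant trace")
    return float(stats.pearsonr(m, e)[0])


# ---------------------------------------------------------------------------
# sweep grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepGrid:
    """Window/threshold exploration grid."""

    window_grid_full: tuple = tuple(range(50, 1051, 100))
    window_grid_short: tuple = tuple(range(50, 551, 100))
    q_grid: tuple = tuple(round(0.2 * i, 1) for i in range(21))  # 0..4 step 0.2
    quantile_grid: tuple = tuple(range(85, 100))  # 85..99 step 1

    def windows_for(self, algorithm: str) -> tuple:
        if algorithm in features.THRESHOLDED:
            return self.window_grid_short
        return self.window_grid_full

    def thresholds_for(self, algorithm: str) -> tuple:
        if algorithm in features.THRESHOLDED:
            return self.q_grid
        if algorithm == "FR":
            return self.quantile_grid
        return (None,)

    def cardinality(self, algorithm: str) -> int:
        return len(self.windows_for(algorithm)) * len(self.thresholds_for(algorithm))


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------


def _segment_context(seg: preprocess.MovementSegment):
    rb = seg.repetition_boundaries
    rest_mav = preprocess.estimate_rest_mav(seg).mav_rest
    first_period = seg.samples[rb[0] : rb[1]]
    measured = preprocess.normalize_phase(seg.force, (int(rb[0]), int(rb[2])))
    return rb, rest_mav, first_period, measured


def evaluate_cell(
    seg: preprocess.MovementSegment,
    algorithm: str,
    window: features.WindowSpec,
    threshold: features.ThresholdSpec | None,
    series: features.FeatureSeries | None = None,
) -> tuple[float, float]:
    """Run filter-output -> feature -> calibrate -> estimate -> metrics for
    one grid cell; returns (rmse_percent, pearson_r)."""
    rb, rest_mav, first_period, measured = _segment_context(seg)
    if series is None:
        thr = None
        if threshold is not None:
            thr = threshold.resolve(algorithm, rest_mav=rest_mav, reference_signal=first_period)
        series = features.sliding_apply(seg.samples, algorithm, window, thr)
    model = control.calibrate(series, rb, segment_id=seg.segment_id)
    est = control.estimate_force(series, model)
    meas = measured[est.sample_index]
    return rmse_percent(meas, est.values), zero_lag_pearson(meas, est.values)


def run_sweep(
    segments,
    algorithms=features.ALGORITHMS,
    grid: SweepGrid | None = None,
    increment_ms: float = 10.0,
) -> pd.DataFrame:
    """Brute-force sweep: every segment x algorithm x grid point.

    Segments must carry their paired force trace (see
    :func:`iemgprop.preprocess.attach_forces`).  Returns a tidy frame with
    one row per cell; failed cells carry NaN metrics and an error message.
    """
    grid = grid or SweepGrid()
    rows = []
    for seg in segments:
        if seg.force is None:
            raise ValueError(f"segment {seg.segment_id} has no paired force trace")
        fs = seg.sampling_rate
        inc = max(1, int(round(increment_ms * fs / 1000.0)))
        rb, rest_mav, first_period, measured = _segment_context(seg)
        spectral_wanted = [a for a in algorithms if a in features.SPECTRAL]
        spectral_cache: dict[float, dict] = {}
        for algorithm in algorithms:
            for wms in grid.windows_for(algorithm):
                window = features.WindowSpec(width_ms=wms, sampling_rate=fs, increment_samples=inc)
                shared_series = None
                if algorithm in features.SPECTRAL:
                    if wms not in spectral_cache:
                        spectral_cache[wms] = features.sliding_spectral_set(
                            seg.samples, window, spectral_wanted
                        )
                    shared_series = spectral_cache[wms][algorithm]
                for thr_param in grid.thresholds_for(algorithm):
                    rec = {
                        "segment_id": seg.segment_id,
                        "movement": seg.movement,
                        "iemg_channel": seg.iemg_channel,
                        "quality": seg.quality,
                        "algorithm": algorithm,
                        "window_ms": float(wms),
                        "threshold": np.nan if thr_param is None else float(thr_param),
                        "rmse_percent": np.nan,
                        "pearson_r": np.nan,
                        "error": "",
                    }
                    try:
                        threshold = _make_threshold(algorithm, thr_param)
                        r, p = evaluate_cell(seg, algorithm, window, threshold, series=shared_series)
                        rec["rmse_percent"], rec["pearson_r"] = r, p
                    except (ValueError, FloatingPointError) as exc:
                        rec["error"] = str(exc)
                    rows.append(rec)
    return pd.DataFrame(rows)


def _make_threshold(algorithm: str, thr_param) -> features.ThresholdSpec | None:
    if algorithm in features.THRESHOLDED:
        return features.ThresholdSpec(kind="dead_zone", q_multiplier=float(thr_param))
    if algorithm == "FR":
        return features.ThresholdSpec(kind="quantile", quantile=float(thr_param))
    return None


def best_per_algorithm(results: pd.DataFrame) -> pd.DataFrame:
    """Minimal-RMSE grid point per (segment, algorithm); ties broken by the
    smaller window (lower latency), then the smaller threshold."""
    if results.empty:
        raise ValueError("empty sweep results")
    ok = results[results["rmse_percent"].notna()].copy()
    ok["_thr"] = ok["threshold"].fillna(-1.0)
    ok = ok.sort_values(["rmse_percent", "window_ms", "_thr"], kind="mergesort")
    best = ok.groupby(["segment_id", "algorithm"], as_index=False, sort=False).head(1)
    return best.drop(columns="_thr").reset_index(drop=True)


def summarize(results: pd.DataFrame, value_cols=("rmse_percent", "pearson_r")) -> pd.DataFrame:
    """Per-algorithm median and quartiles, excluding 'poor'-quality segments
    when a quality column is present."""
    if results.empty:
        raise ValueError("nothing to summarize")
    df = results
    if "quality" in df.columns:
        df = df[df["quality"] != "poor"]
    out = []
    for alg, grp in df.groupby("algorithm", sort=False):
        row = {"algorithm": alg, "n": len(grp)}
        for col in value_cols:
            v = grp[col].dropna().to_numpy()
            if v.size:
                row[f"{col}_median"] = float(np.median(v))
                row[f"{col}_q1"] = float(np.percentile(v, 25))
                row[f"{col}_q3"] = float(np.percentile(v, 75))
            else:
                row[f"{col}_median"] = row[f"{col}_q1"] = row[f"{col}_q3"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def lilliefors_normality(sample) -> tuple[float, float]:
    """Lilliefors-corrected KS test against a normal with estimated moments."""
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("Lilliefors test needs n >= 5")
    if np.ptp(x) == 0:
        raise ValueError("Lilliefors test degenerate for a constant sample")
    from statsmodels.stats.diagnostic import lilliefors as _lf

    stat, p = _lf(x, dist="norm")
    return float(stat), float(p)


@dataclass
class ComparisonTable:
    """Pairwise algorithm comparison after a Friedman omnibus test."""

    algorithms: tuple
    mean_ranks: np.ndarray
    statistic: float
    p_omnibus: float
    p_matrix: np.ndarray  # Bonferroni-corrected pairwise p-values
    significant: np.ndarray  # symmetric bool matrix, empty diagonal
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.significant, index=self.algorithms, columns=self.algorithms)

    def flagged_pairs(self) -> list[tuple[str, str]]:
        k = len(self.algorithms)
        return [
            (self.algorithms[i], self.algorithms[j])
            for i in range(k)
            for j in range(i + 1, k)
            if self.significant[i, j]
        ]


def friedman_bonferroni(
    metric_matrix,
    algorithms=None,
    alpha: float = 0.05,
    require_omnibus: bool = True,
) -> ComparisonTable:
    """Friedman test on within-block ranks plus Dunn-type Bonferroni post hoc.

    ``metric_matrix`` is blocks x algorithms (complete blocks required).
    Pairwise mean-rank differences are compared with the normal
    approximation ``z = |R_i - R_j| / sqrt(k(k+1)/(6n))`` and Bonferroni
    correction over all pairs.
    """
    X = np.asarray(metric_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("metric matrix must be blocks x algorithms")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 blocks and >= 2 algorithms")
    if np.isnan(X).any():
        raise ValueError("missing cells: complete blocks required")
    algorithms = tuple(algorithms) if algorithms is not None else tuple(f"A{i}" for i in range(k))
    if len(algorithms) != k:
        raise ValueError("algorithm labels do not match the matrix width")

    ranks = stats.rankdata(X, axis=1)
    mean_ranks = ranks.mean(axis=0)
    if np.ptp(ranks, axis=1).max() == 0:  # all columns identical
        statistic, p_omnibus = 0.0, 1.0
    elif k == 2:  # textbook chi-square (scipy needs k >= 3)
        statistic = 12.0 * n / (k * (k + 1)) * float(np.sum((mean_ranks - (k + 1) / 2.0) ** 2))
        p_omnibus = float(stats.chi2.sf(statistic, k - 1))
    else:
        statistic, p_omnibus = stats.friedmanchisquare(*(X[:, j] for j in range(k)))
    n_pairs = k * (k - 1) // 2
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    z = diff / se
    p_raw = 2.0 * stats.norm.sf(z)
    p_corr = np.minimum(1.0, p_raw * n_pairs)
    np.fill_diagonal(p_corr, 1.0)
    significant = p_corr < alpha
    if require_omnibus and not (p_omnibus < alpha):
        significant = np.zeros_like(significant)
    np.fill_diagonal(significant, False)
    return ComparisonTable(
        algorithms=algorithms,
        mean_ranks=mean_ranks,
        statistic=float(statistic),
        p_omnibus=float(p_omnibus),
        p_matrix=p_corr,
        significant=significant,
        alpha=alpha,
    )
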