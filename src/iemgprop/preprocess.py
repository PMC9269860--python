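"""Pre-processing: powerline comb filtering, cue-based segmentation, force
phase splitting and normalization, rest-noise estimation, and RMSE-based
pairing of iEMG channels with force gauges and movements.

The comb filter is a cascade of third-order Butterworth band-stop sections,
one per powerline harmonic (50 Hz base, +/- 2 Hz stopband).  It defaults to
causal operation because the pipeline targets online use; zero-phase
(forward-backward) filtering is available for offline parity studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt, sosfiltfilt, sosfreqz

from . import features
from .synth import SessionRecord


# ---------------------------------------------------------------------------
# comb filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CombFilterSpec:
    f0: float = 50.0
    delta_f: float = 2.0
    order: int = 3
    n_harmonics: int | None = None  # None -> every harmonic below 0.9 x Nyquist
    mode: str = "causal"  # 'causal' | 'zero-phase'

    def __post_init__(self) -> None:
        if self.f0 - self.delta_f <= 0:
            raise ValueError("f0 - delta_f must be positive")
        if self.mode not in ("causal", "zero-phase"):
            raise ValueError("mode must be 'causal' or 'zero-phase'")

    def harmonics(self, sampling_rate: float) -> list[float]:
        nyq = sampling_rate / 2.0
        if self.n_harmonics is None:
            n = int(math.floor((0.9 * nyq - self.delta_f) / self.f0))
            n = max(1, n)
        else:
            n = self.n_harmonics
        freqs = [k * self.f0 for k in range(1, n + 1)]
        if freqs[-1] + self.delta_f >= nyq:
            raise ValueError("comb harmonic at or above the Nyquist frequency")
        return freqs


def design_powerline_comb(spec: CombFilterSpec, sampling_rate: float) -> np.ndarray:
    """Cascade (stacked SOS) of band-stop sections at each harmonic k*f0."""
    sections = []
    for fk in spec.harmonics(sampling_rate):
        sos = butter(
            spec.order,
            [fk - spec.delta_f, fk + spec.delta_f],
            btype="bandstop",
            fs=sampling_rate,
            output="sos",
        )
        sections.append(sos)
    out = np.vstack(sections)
    poles_ok = all(np.all(np.abs(np.roots(s[3:])) < 1.0) for s in out)
    if not poles_ok:
        raise ValueError("unstable comb filter section")
    return out


def comb_response_db(sos: np.ndarray, freqs, sampling_rate: float) -> np.ndarray:
    """Magnitude response (dB) of the cascade at the given frequencies."""
    _, h = sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs, float)), fs=sampling_rate)
    return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def apply_filter(signal, sos: np.ndarray, mode: str = "causal") -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.size <= 6 * sos.shape[0]:
        raise ValueError("signal shorter than the filter warm-up length")
    if mode == "causal":
        return sosfilt(sos, x)
    if mode == "zero-phase":
        return sosfiltfilt(sos, x)
    raise ValueError("mode must be 'causal' or 'zero-phase'")


def filter_session(session: SessionRecord, spec: CombFilterSpec | None = None) -> np.ndarray:
    """Comb-filter every iEMG channel; returns a channels x samples array."""
    spec = spec or CombFilterSpec()
    sos = design_powerline_comb(spec, session.protocol.sampling_rate)
    return np.vstack([apply_filter(ch, sos, spec.mode) for ch in session.iemg])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

REST_WINDOW_MS = 100.0  # leading rest window used for noise estimation


@dataclass
class MovementSegment:
    """One movement on one iEMG channel: filtered samples, the leading
    100 ms rest window, the tracking-period boundaries, and (once paired)
    the phase-specific force trace of the associated gauge."""

    movement: str
    iemg_channel: int
    samples: np.ndarray
    rest_window: np.ndarray
    repetition_boundaries: np.ndarray  # R+1 within-segment indices
    sampling_rate: float
    force: np.ndarray | None = None
    gauge: int | None = None
    phase: str | None = None
    segment_id: str = ""
    quality: str = "good"

    @property
    def repetitions(self) -> int:
        return self.repetition_boundaries.size - 1


@dataclass(frozen=True)
class RestNoise:
    mav_rest: float

    def __post_init__(self) -> None:
        if self.mav_rest < 0:
            raise ValueError("mav_rest must be non-negative")


def segment_by_cues(session: SessionRecord, iemg: np.ndarray | None = None) -> list[MovementSegment]:
    """One segment per (movement, channel), from the cue labels.

    Pass the comb-filtered iEMG as ``iemg``; defaults to the raw channels.
    """
    iemg = session.iemg if iemg is None else iemg
    p = session.protocol
    fs = p.sampling_rate
    n_rest100 = int(round(REST_WINDOW_MS * fs / 1000.0))
    segments: list[MovementSegment] = []
    for label, (a, b) in session.movement_slices.items():
        n_rest = p.rest_samples
        period = p.period_samples
        n_periods = (b - a - n_rest) // period
        if n_periods < 3:
            raise ValueError(f"movement {label!r} has < 3 tracking periods; calibration impossible")
        boundaries = n_rest + period * np.arange(n_periods + 1, dtype=np.int64)
        for c in range(session.n_channels):
            x = np.asarray(iemg[c, a:b], dtype=float)
            quality = "good"
            if session.channel_quality is not None:
                quality = session.channel_quality[c]
            segments.append(
                MovementSegment(
                    movement=label,
                    iemg_channel=c,
                    samples=x,
                    rest_window=x[:n_rest100],
                    repetition_boundaries=boundaries,
                    sampling_rate=fs,
                    segment_id=f"s{session.seed}:ch{c}:{label}",
                    quality=quality,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# force handling
# ---------------------------------------------------------------------------


def split_force_phases(force_signal) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) phases; ``positive - negative`` reconstructs the
    input exactly."""
    x = np.asarray(force_signal, dtype=float)
    return np.clip(x, 0.0, None), np.clip(-x, 0.0, None)


def normalize_phase(force_phase_signal, calibration_span: tuple[int, int]) -> np.ndarray:
    """Divide a (non-negative) phase trace by its maximum over the
    calibration span; later samples may exceed 1."""
    x = np.asarray(force_phase_signal, dtype=float)
    a, b = calibration_span
    m = float(np.max(x[a:b])) if b > a else 0.0
    if m <= 0:
        raise ValueError("dead gauge: zero maximum over the calibration span")
    return x / m


def estimate_rest_mav(segment: MovementSegment) -> RestNoise:
    """Resting-noise level: MAV of the segment's leading 100 ms."""
    if segment.rest_window.size == 0:
        raise ValueError("segment has no rest window")
    return RestNoise(mav_rest=float(np.mean(np.abs(segment.rest_window))))


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


@dataclass
class PairingTable:
    """Per-channel best (gauge, phase, movement) assignment with the RMSE of
    the normalized MAV fit that selected it."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def row_for(self, channel: int) -> dict:
        r = self.frame[self.frame.iemg_channel == channel]
        if r.empty:
            raise KeyError(f"no pairing row for channel {channel}")
        return r.iloc[0].to_dict()


def pair_channels(
    session: SessionRecord,
    iemg: np.ndarray | None = None,
    window_ms: float = 250.0,
    increment_ms: float = 50.0,
) -> PairingTable:
    """RMSE-refined pairing: for every iEMG channel, the (gauge, phase,
    movement) candidate whose normalized force trace best matches the
    channel's normalized MAV estimate (both normalized over the first two
    tracking periods) is selected."""
    if session.n_channels < 1 or session.n_gauges < 1:
        raise ValueError("need at least one channel and one gauge")
    iemg = session.iemg if iemg is None else iemg
    p = session.protocol
    fs = p.sampling_rate
    window = features.WindowSpec(
        width_ms=window_ms,
        sampling_rate=fs,
        increment_samples=max(1, int(round(increment_ms * fs / 1000.0))),
    )
    rows = []
    for c in range(session.n_channels):
        best = None
        for label, (a, b) in session.movement_slices.items():
            x = np.asarray(iemg[c, a:b], dtype=float)
            n_rest = p.rest_samples
            period = p.period_samples
            rb = (n_rest, n_rest + period, n_rest + 2 * period)
            series = features.sliding_apply(x, "MAV", window)
            cal = (series.sample_index >= rb[0]) & (series.sample_index < rb[2])
            if not cal.any():
                continue
            scale = float(np.max(series.values[cal]))
            if scale <= 0:
                continue
            mask = series.sample_index >= rb[0]
            est = series.values[mask] / scale
            at = series.sample_index[mask]
            for g in range(session.n_gauges):
                fsig = np.asarray(session.force[g, a:b], dtype=float)
                pos, neg = split_force_phases(fsig)
                for phase_name, ph in (("positive", pos), ("negative", neg)):
                    try:
                        pn = normalize_phase(ph, (rb[0], rb[2]))
                    except ValueError:
                        continue
                    err = est - pn[at]
                    rmse = float(np.sqrt(np.mean(err * err)))
                    cand = (rmse, g, phase_name, label)
                    if best is None or rmse < best[0]:
                        best = cand
        if best is None:
            raise ValueError(f"channel {c}: no valid pairing candidate")
        rows.append(
            {
                "iemg_channel": c,
                "force_gauge": best[1],
                "phase": best[2],
                "movement": best[3],
                "rmse_of_mav_fit": best[0],
            }
        )
    frame = pd.DataFrame(rows).sort_values("iemg_channel").reset_index(drop=True)
    return PairingTable(frame=frame)


def attach_forces(segments: list[MovementSegment], session: SessionRecord,
                  pairing: PairingTable) -> list[MovementSegment]:
    """Keep each channel's paired movement segment and attach the paired
    gauge's phase-specific force trace; segments for other (channel,
    movement) combinations are dropped."""
    out = []
    for seg in segments:
        try:
            row = pairing.row_for(seg.iemg_channel)
        except KeyError:
            continue
        if seg.movement != row["movement"]:
            continue
        a, b = session.movement_slices[seg.movement]
        fsig = np.asarray(session.force[int(row["force_gauge"]), a:b], dtype=float)
        pos, neg = split_force_phases(fsig)
        seg.force = pos if row["phase"] == "positive" else neg
        seg.gauge = int(row["force_gauge"])
        seg.phase = row["phase"]
        out.append(seg)
    return out
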