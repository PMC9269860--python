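"""Synthetic intramuscular EMG / force session generator.

Emulates a sine-tracking myocontrol recording session: a subject follows a
0.1 Hz force sine at 20 % of maximal voluntary contraction (MVC) for a number
of repetitions per movement, while differential fine-wire iEMG is sampled at
10 kHz and a bank of force gauges records the elicited joint forces.

The muscle model is a standard recruitment / rate-coding motor-unit pool:
each unit has a recruitment threshold (fraction of MVC), fires above it at

    rate = min(peak_rate, min_rate + rate_slope * (excitation - threshold))

with inter-spike-interval variability given by a coefficient of variation,
and contributes a stereotyped motor-unit action potential (MUAP) waveform to
the recorded channel.  Broadband amplifier noise and 50 Hz powerline
interference (with harmonics) are superimposed.  Every source of randomness
is driven by an explicit seed, so sessions are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

POWERLINE_HZ = 50.0


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Movement:
    """One commanded movement: its label, force gauge and force-phase sign."""

    label: str
    gauge: int
    sign: int  # +1 -> positive force phase, -1 -> negative

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("movement sign must be +1 or -1")
        if self.gauge < 0:
            raise ValueError("gauge index must be non-negative")


def _default_movements() -> tuple[Movement, ...]:
    # three joints, flexion/extension (or pronation/supination) pairs; gauge
    # indices follow the physical layout of the measurement device: fingers
    # D2..D5 on gauges 0..3, thumb on 4-5, wrist on 6-8.
    return (
        Movement("D2_flex", 0, +1),
        Movement("D2_ext", 0, -1),
        Movement("D3_flex", 1, +1),
        Movement("D3_ext", 1, -1),
        Movement("wrist_pro", 6, +1),
        Movement("wrist_sup", 6, -1),
    )


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and amplitude parameters of the sine-tracking protocol."""

    sampling_rate: float = 10_000.0
    sine_frequency: float = 0.1
    sine_amplitude_fraction: float = 0.2
    repetitions: int = 10
    rest_duration: float = 1.0
    n_gauges: int = 9
    movements: tuple[Movement, ...] = field(default_factory=_default_movements)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.sine_amplitude_fraction <= 1:
            raise ValueError("sine_amplitude_fraction must be in (0, 1]")
        if self.repetitions < 3:
            raise ValueError("need >= 3 repetitions (2 calibrate + >= 1 evaluate)")
        if self.rest_duration < 0.1:
            raise ValueError("rest_duration must be >= 0.1 s")
        if self.sine_frequency <= 0:
            raise ValueError("sine_frequency must be positive")
        if not self.movements:
            raise ValueError("protocol needs at least one movement")
        gauges = [m.gauge for m in self.movements]
        if max(gauges) >= self.n_gauges:
            raise ValueError("movement gauge index exceeds n_gauges")

    # -- derived sample counts ------------------------------------------------
    @property
    def rest_samples(self) -> int:
        return int(round(self.rest_duration * self.sampling_rate))

    @property
    def period_samples(self) -> int:
        return int(round(self.sampling_rate / self.sine_frequency))

    @property
    def tracking_samples(self) -> int:
        return self.repetitions * self.period_samples

    @property
    def segment_samples(self) -> int:
        return self.rest_samples + self.tracking_samples

    @property
    def total_samples(self) -> int:
        return self.segment_samples * len(self.movements)

    def movement_by_label(self, label: str) -> Movement:
        for m in self.movements:
            if m.label == label:
                return m
        raise ValueError(f"unknown movement label: {label!r}")


# ---------------------------------------------------------------------------
# motor units
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MuapTemplate:
    """One unit's action-potential waveform (uV), sampled at ``sampling_rate``."""

    waveform: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", w)
        peak = np.max(np.abs(w)) if w.size else 0.0
        if peak > 0 and abs(w.sum()) > 1e-6 * peak * w.size:
            raise ValueError("MUAP waveform must integrate to ~zero")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.waveform.size / self.sampling_rate

    @property
    def peak_amplitude(self) -> float:
        return float(np.max(np.abs(self.waveform)))


def gaussian_muap(
    peak_amplitude: float,
    duration_ms: float = 5.0,
    sampling_rate: float = 10_000.0,
    phases: int = 2,
) -> MuapTemplate:
    """Biphasic (``phases=2``) or triphasic (``phases=3``) zero-mean MUAP shape
    built from derivatives of a Gaussian."""
    n = max(3, int(round(duration_ms * sampling_rate / 1000.0)))
    t = np.linspace(-3.0, 3.0, n)
    g = np.exp(-0.5 * t * t)
    if phases == 2:
        w = -t * g
    elif phases == 3:
        w = (t * t - 1.0) * g
    else:
        raise ValueError("phases must be 2 or 3")
    w = w - w.mean()
    w *= peak_amplitude / np.max(np.abs(w))
    return MuapTemplate(w, sampling_rate)


@dataclass(frozen=True)
class MotorUnit:
    recruitment_threshold: float
    min_rate: float
    peak_rate: float
    rate_slope: float
    isi_cv: float
    template: MuapTemplate

    def __post_init__(self) -> None:
        if not 0 <= self.recruitment_threshold < 1:
            raise ValueError("recruitment_threshold must be in [0, 1)")
        if self.min_rate >= self.peak_rate:
            raise ValueError("min_rate must be < peak_rate")
        if self.isi_cv < 0:
            raise ValueError("isi_cv must be >= 0")


def make_motor_units(
    n_units: int,
    seed,
    sampling_rate: float = 10_000.0,
    threshold_range: tuple[float, float] = (0.0, 0.5),
    min_rate: float = 8.0,
    peak_rate: float = 35.0,
    rate_slope: float = 40.0,
    isi_cv: float = 0.15,
    amplitude_median_uv: float = 60.0,
    amplitude_sigma: float = 0.5,
) -> tuple[MotorUnit, ...]:
    """Draw a conventional motor-unit pool: thresholds uniform over
    ``threshold_range``, lognormal MUAP amplitudes, alternating bi/triphasic
    templates."""
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_units):
        thr = float(rng.uniform(*threshold_range))
        amp = float(amplitude_median_uv * np.exp(amplitude_sigma * rng.standard_normal()))
        tpl = gaussian_muap(amp, sampling_rate=sampling_rate, phases=2 + (i % 2))
        units.append(
            MotorUnit(
                recruitment_threshold=thr,
                min_rate=min_rate,
                peak_rate=peak_rate,
                rate_slope=rate_slope,
                isi_cv=isi_cv,
                template=tpl,
            )
        )
    return tuple(units)


def proportional_units(
    n_units: int,
    seed,
    sampling_rate: float = 10_000.0,
    rate_per_excitation: float = 125.0,
    peak_rate: float = 60.0,
    isi_cv: float = 0.15,
    amplitude_median_uv: float = 60.0,
    amplitude_sigma: float = 0.5,
) -> tuple[MotorUnit, ...]:
    """A pool whose aggregate drive is proportional to excitation: every
    unit has zero recruitment threshold and a rate linear in excitation, so
    the time-averaged rectified iEMG scales with the driving force."""
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_units):
        amp = float(amplitude_median_uv * np.exp(amplitude_sigma * rng.standard_normal()))
        tpl = gaussian_muap(amp, sampling_rate=sampling_rate, phases=2 + (i % 2))
        units.append(
            MotorUnit(
                recruitment_threshold=0.0,
                min_rate=0.0,
                peak_rate=peak_rate,
                rate_slope=rate_per_excitation,
                isi_cv=isi_cv,
                template=tpl,
            )
        )
    return tuple(units)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Additive recording noise: broadband baseline plus powerline harmonics."""

    baseline_rms: float = 3.0  # uV
    powerline_amplitude: float = 50.0  # uV at 50 Hz
    harmonic_decay: float = 0.5  # amplitude ratio per harmonic
    n_harmonics: int = 5

    def __post_init__(self) -> None:
        if min(self.baseline_rms, self.powerline_amplitude, self.harmonic_decay) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be non-negative")


SILENT = NoiseSpec(baseline_rms=0.0, powerline_amplitude=0.0)


# ---------------------------------------------------------------------------
# force profile
# ---------------------------------------------------------------------------


def make_force_profile(
    protocol: ProtocolSpec,
    movement: str,
    seed=0,
    tracking_noise: bool = True,
    tracking_noise_rms: float = 0.02,
    tracking_noise_cutoff_hz: float = 1.0,
) -> np.ndarray:
    """Per-sample target force (fraction of MVC) for one movement segment.

    The trace is zero during the leading rest interval, then follows the
    movement's phase of the tracking sine (positive-phase movements follow
    max(sin, 0), negative-phase movements max(-sin, 0)).  A smooth tracking
    error (low-pass filtered Gaussian noise, 2 % MVC RMS by default) emulates
    imperfect human tracking; the result is clipped at zero.
    """
    mv = protocol.movement_by_label(movement)
    n_rest = protocol.rest_samples
    n_track = protocol.tracking_samples
    t = np.arange(n_track) / protocol.sampling_rate
    s = np.sin(2.0 * np.pi * protocol.sine_frequency * t)
    target = protocol.sine_amplitude_fraction * np.clip(mv.sign * s, 0.0, None)
    if tracking_noise and tracking_noise_rms > 0:
        rng = np.random.default_rng(seed)
        sos = butter(2, tracking_noise_cutoff_hz, fs=protocol.sampling_rate, output="sos")
        # causal low-pass with a discarded warm-up margin: no edge artifacts
        margin = int(5 * protocol.sampling_rate / tracking_noise_cutoff_hz)
        w = rng.standard_normal(n_track + margin)
        e = sosfilt(sos, w)[margin:]
        e_rms = float(np.sqrt(np.mean(e * e)))
        if e_rms > 0:
            e = e * (tracking_noise_rms / e_rms)
        target = np.clip(target + e, 0.0, None)
    return np.concatenate([np.zeros(n_rest), target])


# ---------------------------------------------------------------------------
# spike trains and rendering
# ---------------------------------------------------------------------------


def _active_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, stop) runs where ``mask`` is True."""
    m = mask.astype(np.int8)
    edges = np.flatnonzero(np.diff(m))
    starts = list(edges[m[edges] == 0] + 1)
    stops = list(edges[m[edges] == 1] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def simulate_spike_trains(
    units,
    excitation: np.ndarray,
    sampling_rate: float,
    seed=0,
) -> list[np.ndarray]:
    """Per-unit spike sample indices driven by a common excitation trace.

    A unit fires only while ``excitation >= recruitment_threshold``; its
    instantaneous rate follows the linear rate-coding law capped at
    ``peak_rate``; inter-spike intervals are jittered with the unit's ISI
    coefficient of variation (Gaussian multiplicative jitter, floored at
    0.1 of the mean interval to keep intervals positive).
    """
    units = list(units)
    if not units:
        raise ValueError("empty motor-unit list")
    exc = np.asarray(excitation, dtype=float)
    if exc.min() < -1e-9 or exc.max() > 1 + 1e-9:
        raise ValueError("excitation must lie in [0, 1]")
    base = [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]
    trains: list[np.ndarray] = []
    for i, u in enumerate(units):
        rng = np.random.default_rng(base + [i])
        mask = exc >= u.recruitment_threshold
        spikes: list[np.ndarray] = []
        if mask.any():
            for a, b in _active_runs(mask):
                # time rescaling: integrate the instantaneous rate and place
                # spikes where the integral crosses unit-mean jittered targets
                r = u.min_rate + u.rate_slope * (exc[a:b] - u.recruitment_threshold)
                np.clip(r, 0.0, u.peak_rate, out=r)
                R = np.cumsum(r) / sampling_rate
                total = float(R[-1])
                if total <= 0:
                    continue
                if u.isi_cv > 0:
                    incs = np.maximum(0.1, 1.0 + u.isi_cv * rng.standard_normal(int(total * 1.5) + 10))
                    targets = np.cumsum(incs)
                    while targets[-1] < total:
                        more = np.maximum(0.1, 1.0 + u.isi_cv * rng.standard_normal(10))
                        targets = np.concatenate([targets, targets[-1] + np.cumsum(more)])
                else:
                    targets = np.arange(1.0, total + 1.0)
                targets = targets[targets <= total]
                spikes.append(a + np.searchsorted(R, targets))
        trains.append(
            np.concatenate(spikes).astype(np.int64) if spikes else np.asarray([], dtype=np.int64)
        )
    return trains


def render_iemg(
    spike_trains,
    templates,
    noise: NoiseSpec,
    n_samples: int,
    sampling_rate: float,
    seed=0,
) -> np.ndarray:
    """Single-channel iEMG (uV): spike trains rendered through their MUAP
    templates plus baseline noise and powerline harmonics."""
    out = np.zeros(n_samples, dtype=float)
    for spikes, tpl in zip(spike_trains, templates):
        w = tpl.waveform
        if w.size >= n_samples:
            raise ValueError("template longer than the signal")
        for s in spikes:
            s = int(s)
            if s >= n_samples:
                continue
            e = min(n_samples, s + w.size)
            out[s:e] += w[: e - s]
    rng = np.random.default_rng(seed)
    if noise.baseline_rms > 0:
        out += rng.normal(0.0, noise.baseline_rms, n_samples)
    if noise.powerline_amplitude > 0 and noise.n_harmonics > 0:
        t = np.arange(n_samples) / sampling_rate
        for k in range(1, noise.n_harmonics + 1):
            amp = noise.powerline_amplitude * noise.harmonic_decay ** (k - 1)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            out += amp * np.sin(2.0 * np.pi * POWERLINE_HZ * k * t + phi)
    return out


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelConfig:
    """One iEMG channel: its agonist movement, motor-unit pool and the gain
    with which every other movement's excitation leaks into it."""

    agonist: str
    units: tuple[MotorUnit, ...]
    crosstalk_gain: float = 0.1


@dataclass
class SessionRecord:
    """One recorded (or synthesized) session."""

    iemg: np.ndarray  # channels x samples, uV
    force: np.ndarray  # gauges x samples, arbitrary units
    labels: np.ndarray  # per-sample code: movement index, or -(index+1) for its leading rest
    protocol: ProtocolSpec
    movement_slices: dict  # label -> (start, stop) covering rest + tracking
    ground_truth: dict | None = None  # synthetic only
    seed: int | None = None
    channel_quality: list | None = None  # per-channel 'good'|'questionable'|'poor'

    @property
    def n_channels(self) -> int:
        return self.iemg.shape[0]

    @property
    def n_gauges(self) -> int:
        return self.force.shape[0]

    def validate(self) -> None:
        if self.iemg.shape[1] != self.force.shape[1]:
            raise ValueError("iEMG and force must share sample count")
        if self.labels.shape[0] != self.iemg.shape[1]:
            raise ValueError("labels must cover all samples")
        p = self.protocol
        for label, (a, b) in self.movement_slices.items():
            if b - a != p.segment_samples:
                raise ValueError(f"segment {label!r} has wrong length")
            n_periods = (b - a - p.rest_samples) // p.period_samples
            if n_periods != p.repetitions:
                raise ValueError(f"segment {label!r} does not hold {p.repetitions} periods")


def default_channel_configs(protocol: ProtocolSpec, seed, crosstalk_gain: float = 0.1,
                            units_per_channel: tuple[int, int] = (5, 30)) -> tuple[ChannelConfig, ...]:
    """One channel per movement with a randomly sized motor-unit pool."""
    rng = np.random.default_rng([int(seed), 11])
    configs = []
    for i, mv in enumerate(protocol.movements):
        n_units = int(rng.integers(units_per_channel[0], units_per_channel[1] + 1))
        units = make_motor_units(n_units, [int(seed), 12, i], sampling_rate=protocol.sampling_rate)
        configs.append(ChannelConfig(agonist=mv.label, units=units, crosstalk_gain=crosstalk_gain))
    return tuple(configs)


def assemble_session(
    protocol: ProtocolSpec | None = None,
    channel_configs=None,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    gauge_snr_db: float | None = 20.0,
    tracking_noise: bool = True,
) -> SessionRecord:
    """Assemble a full synthetic session.

    Each iEMG channel is driven primarily by its agonist movement's elicited
    force (excitation = true force, fraction of MVC) plus crosstalk from the
    other movements.  Force gauges record the elicited forces of the movements
    assigned to them, signed by phase, plus white gauge noise at
    ``gauge_snr_db`` relative to each gauge's clean RMS.  The true pairing and
    true per-movement force traces are stored in ``ground_truth``.
    """
    protocol = protocol or ProtocolSpec()
    noise = noise if noise is not None else NoiseSpec()
    if channel_configs is None:
        channel_configs = default_channel_configs(protocol, seed)
    agonists = [c.agonist for c in channel_configs]
    if len(set(agonists)) != len(agonists):
        raise ValueError("duplicate agonist assignment across channels")
    for a in agonists:
        protocol.movement_by_label(a)  # raises on unknown label

    total = protocol.total_samples
    n_seg = protocol.segment_samples
    labels = np.empty(total, dtype=np.int32)
    movement_slices: dict[str, tuple[int, int]] = {}
    traces: dict[str, np.ndarray] = {}
    for m_i, mv in enumerate(protocol.movements):
        a = m_i * n_seg
        b = a + n_seg
        movement_slices[mv.label] = (a, b)
        labels[a : a + protocol.rest_samples] = -(m_i + 1)
        labels[a + protocol.rest_samples : b] = m_i
        traces[mv.label] = make_force_profile(
            protocol, mv.label, seed=[int(seed), 101, m_i], tracking_noise=tracking_noise
        )

    # force gauges -----------------------------------------------------------
    clean = np.zeros((protocol.n_gauges, total), dtype=float)
    for m_i, mv in enumerate(protocol.movements):
        a, b = movement_slices[mv.label]
        clean[mv.gauge, a:b] += mv.sign * traces[mv.label]
    force = clean.copy()
    if gauge_snr_db is not None:
        rng = np.random.default_rng([int(seed), 2])
        g_rms = np.sqrt(np.mean(clean * clean, axis=1))
        noise_rms = g_rms / 10.0 ** (gauge_snr_db / 20.0)
        floor = np.median(noise_rms[noise_rms > 0]) if (noise_rms > 0).any() else 0.0
        noise_rms = np.maximum(noise_rms, floor)
        for g in range(protocol.n_gauges):
            if noise_rms[g] > 0:
                force[g] += rng.normal(0.0, noise_rms[g], total)

    # iEMG channels -----------------------------------------------------------
    iemg = np.zeros((len(channel_configs), total), dtype=float)
    spike_trains: dict[int, list[np.ndarray]] = {}
    for c_i, cfg in enumerate(channel_configs):
        exc = np.zeros(total, dtype=float)
        for mv in protocol.movements:
            a, b = movement_slices[mv.label]
            gain = 1.0 if mv.label == cfg.agonist else cfg.crosstalk_gain
            exc[a:b] += gain * traces[mv.label]
        np.clip(exc, 0.0, 1.0, out=exc)
        trains = simulate_spike_trains(cfg.units, exc, protocol.sampling_rate, seed=_channel_seed(seed, c_i))
        spike_trains[c_i] = trains
        iemg[c_i] = render_iemg(
            trains,
            [u.template for u in cfg.units],
            noise,
            total,
            protocol.sampling_rate,
            seed=[int(seed), 4, c_i],
        )

    ground_truth = {
        "pairing": [
            {
                "iemg_channel": c_i,
                "force_gauge": protocol.movement_by_label(cfg.agonist).gauge,
                "phase": "positive" if protocol.movement_by_label(cfg.agonist).sign > 0 else "negative",
                "movement": cfg.agonist,
            }
            for c_i, cfg in enumerate(channel_configs)
        ],
        "true_force": traces,
        "spike_trains": spike_trains,
    }
    rec = SessionRecord(
        iemg=iemg.astype(np.float32),
        force=force.astype(np.float32),
        labels=labels,
        protocol=protocol,
        movement_slices=movement_slices,
        ground_truth=ground_truth,
        seed=int(seed),
    )
    rec.validate()
    return rec


def _channel_seed(seed: int, channel: int) -> list[int]:
    return [int(seed), 3, channel]


def single_movement_protocol(
    repetitions: int = 10,
    sampling_rate: float = 10_000.0,
    rest_duration: float = 1.0,
) -> ProtocolSpec:
    """A one-movement protocol, convenient for per-segment studies."""
    return ProtocolSpec(
        sampling_rate=sampling_rate,
        repetitions=repetitions,
        rest_duration=rest_duration,
        n_gauges=1,
        movements=(Movement("flex", 0, +1),),
    )
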