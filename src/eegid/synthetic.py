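"""Synthetic multichannel EEG cohorts with subject-specific spectral signatures.

The generator stands in for a private 21-subject database: each subject gets
an individual alpha-peak frequency, per-band amplitudes, and a regional
band-power topography; recordings add 1/f background noise, common-mode
50 Hz powerline interference, and slow drift. Task profiles modulate band
powers to emulate escalating cognitive load (alpha suppression, beta/gamma
enhancement), and the hardest level may terminate early.

Oscillations are band-pass-filtered white noise rather than pure tones, so
no two segments repeat and classification is a genuine learning problem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidCohortError, InvalidProfileError, InvalidProtocolError
from .montage import CHANNELS, CHANNEL_REGION, REGIONS

BANDS: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: fixed band edges in Hz; the alpha band is re-centred per subject
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

ALPHA_LO, ALPHA_HI = 8.0, 13.0
ALPHA_HALF_WIDTH = 1.25  # Hz, half-width of the subject-centred alpha band

TASKS: tuple[str, ...] = ("rest", "level1", "level2", "level3")
TASK_INDEX: dict[str, int] = {t: i for i, t in enumerate(TASKS)}

# population-level regional gain template: alpha dominates posteriorly,
# beta/delta/theta anteriorly, gamma roughly flat
_TOPO_TEMPLATE: dict[str, dict[str, float]] = {
    "F": {"delta": 1.2, "theta": 1.1, "alpha": 0.7, "beta": 1.3, "gamma": 1.0},
    "C": {"delta": 1.0, "theta": 1.0, "alpha": 0.9, "beta": 1.2, "gamma": 1.0},
    "P": {"delta": 0.9, "theta": 1.0, "alpha": 1.3, "beta": 0.9, "gamma": 1.0},
    "O": {"delta": 0.8, "theta": 0.9, "alpha": 1.6, "beta": 0.8, "gamma": 1.0},
}

# population-level band RMS amplitudes in µV
_BASE_AMPLITUDES: dict[str, float] = {
    "delta": 10.0,
    "theta": 6.0,
    "alpha": 18.0,
    "beta": 9.0,
    "gamma": 6.0,
}

# relative strength of per-subject amplitude variability per band.  The
# wide beta/gamma bands carry most of the identity information: their
# per-segment power estimates are statistically stable (many independent
# degrees of freedom per 1 s window), whereas narrowband rhythms fluctuate
# strongly from segment to segment and would act as label noise.
_BAND_JITTER_WEIGHT: dict[str, float] = {
    "delta": 0.3,
    "theta": 0.4,
    "alpha": 0.6,
    "beta": 1.2,
    "gamma": 1.5,
}


@dataclass(frozen=True)
class SubjectSignature:
    """Per-subject spectral fingerprint driving the signal synthesis."""

    subject_id: int
    alpha_peak_hz: float
    band_amplitudes: dict[str, float]
    topography: dict[str, dict[str, float]]
    noise_scale: float
    seed: int

    def __post_init__(self) -> None:
        if not (ALPHA_LO <= self.alpha_peak_hz <= ALPHA_HI):
            raise InvalidCohortError(
                f"alpha_peak_hz {self.alpha_peak_hz} outside [{ALPHA_LO}, {ALPHA_HI}]"
            )
        if any(a <= 0 for a in self.band_amplitudes.values()):
            raise InvalidCohortError("band amplitudes must be strictly positive")
        for region, gains in self.topography.items():
            if any(g <= 0 for g in gains.values()):
                raise InvalidCohortError(f"non-positive topography gain in region {region}")
        if self.noise_scale <= 0:
            raise InvalidCohortError("noise_scale must be strictly positive")


@dataclass(frozen=True)
class TaskLoadProfile:
    """Band-power modulation and nominal duration of one task."""

    task_id: str
    alpha_factor: float
    beta_factor: float
    gamma_factor: float
    duration_s: float
    completion_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.task_id not in TASKS:
            raise InvalidProfileError(f"unknown task_id {self.task_id!r}")
        if min(self.alpha_factor, self.beta_factor, self.gamma_factor) <= 0:
            raise InvalidProfileError("band factors must be strictly positive")
        if self.duration_s <= 0:
            raise InvalidProfileError("duration_s must be strictly positive")
        if not (0.0 < self.completion_prob <= 1.0):
            raise InvalidProfileError("completion_prob must be in (0, 1]")

    def band_factor(self, band: str) -> float:
        return {"alpha": self.alpha_factor, "beta": self.beta_factor, "gamma": self.gamma_factor}.get(band, 1.0)


@dataclass
class Recording:
    """One subject x task multichannel signal in µV."""

    subject_id: int
    task_id: str
    channel_labels: list[str]
    fs_hz: float
    data: np.ndarray  # channels x time
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise InvalidProtocolError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidProtocolError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def default_profiles(
    duration_s: float = 60.0, level3_completion_prob: float = 13.0 / 21.0
) -> list[TaskLoadProfile]:
    """The four-task acquisition protocol: rest then three game levels of
    rising difficulty.  Alpha power drops and beta/gamma rise with load;
    the hardest level is completed with probability ``level3_completion_prob``."""
    return [
        TaskLoadProfile("rest", 1.5, 0.8, 0.7, duration_s),
        TaskLoadProfile("level1", 1.0, 1.0, 1.0, duration_s),
        TaskLoadProfile("level2", 0.8, 1.2, 1.3, duration_s),
        TaskLoadProfile("level3", 0.6, 1.45, 1.6, duration_s, level3_completion_prob),
    ]


@dataclass(frozen=True)
class CohortPreset:
    """Knobs controlling how distinguishable subjects are from one another.

    ``alpha_dispersion_hz`` is the half-spread of individual alpha peaks
    around 10.5 Hz; ``amplitude_jitter`` and ``topo_jitter`` are log-scale
    standard deviations of per-subject band-amplitude and regional-gain
    multipliers (amplitude jitter is additionally weighted per band);
    ``noise_scale_range`` bounds the 1/f background RMS in µV.
    """

    alpha_dispersion_hz: float = 2.4
    amplitude_jitter: float = 1.2
    topo_jitter: float = 0.6
    noise_scale_range: tuple[float, float] = (0.3, 1.0)


STRONG_PRESET = CohortPreset()
WEAK_PRESET = CohortPreset(
    alpha_dispersion_hz=0.8,
    amplitude_jitter=0.6,
    topo_jitter=0.3,
    noise_scale_range=(4.0, 6.0),
)

_PRESETS = {"strong": STRONG_PRESET, "weak": WEAK_PRESET}


def make_cohort(
    n_subjects: int, seed: int, preset: str | CohortPreset = "strong"
) -> list[SubjectSignature]:
    """Draw ``n_subjects`` pairwise-distinct signatures, deterministically.

    Alpha peaks are spread over an interval centred at 10.5 Hz (width set by
    the preset's dispersion) and assigned in a shuffled order so subject id
    carries no frequency information.
    """
    if n_subjects < 2:
        raise InvalidCohortError(f"a cohort needs at least 2 subjects, got {n_subjects}")
    cfg = _PRESETS[preset] if isinstance(preset, str) else preset
    rng = np.random.default_rng(seed)

    centre = 0.5 * (ALPHA_LO + ALPHA_HI)
    spread = min(cfg.alpha_dispersion_hz, centre - ALPHA_LO - 0.1)
    grid = centre + spread * np.linspace(-1.0, 1.0, n_subjects)
    grid = grid + rng.uniform(-0.3, 0.3, n_subjects) * (spread / max(n_subjects - 1, 1))
    rng.shuffle(grid)
    grid = np.clip(grid, ALPHA_LO + 1e-3, ALPHA_HI - 1e-3)

    signatures = []
    for sid in range(n_subjects):
        amps = {
            b: _BASE_AMPLITUDES[b]
            * float(np.exp(rng.normal(0.0, cfg.amplitude_jitter * _BAND_JITTER_WEIGHT[b])))
            for b in BANDS
        }
        topo = {
            r: {
                b: _TOPO_TEMPLATE[r][b] * float(np.exp(rng.normal(0.0, cfg.topo_jitter)))
                for b in BANDS
            }
            for r in REGIONS
        }
        signatures.append(
            SubjectSignature(
                subject_id=sid,
                alpha_peak_hz=float(grid[sid]),
                band_amplitudes=amps,
                topography=topo,
                noise_scale=float(rng.uniform(*cfg.noise_scale_range)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return signatures


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float, fs: float) -> np.ndarray:
    """Unit-RMS band-limited noise via zero-phase Butterworth filtering."""
    pad = int(fs)  # discard one second of filter transient on each side
    white = rng.standard_normal(n + 2 * pad)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)[pad : pad + n]
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-12)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-12)


def _alpha_edges(peak_hz: float) -> tuple[float, float]:
    lo = max(peak_hz - ALPHA_HALF_WIDTH, ALPHA_LO - 0.5)
    hi = min(peak_hz + ALPHA_HALF_WIDTH, ALPHA_HI + 0.5)
    return lo, hi


def simulate_recording(
    sig: SubjectSignature,
    profile: TaskLoadProfile,
    fs_hz: float = 1000.0,
    powerline_amp: float = 2.0,
    seed: int = 0,
) -> Recording:
    """Synthesize one subject x task recording.

    The signal per channel is a sum over bands of band-limited noise with
    RMS ``band_amplitude * regional_gain * task_factor``, plus 1/f
    background, a common-mode 50 Hz sinusoid, a constant offset, and a
    0.1 Hz drift.  The hardest level is truncated to a uniform fraction in
    [0.4, 1] of its nominal duration when the completion draw fails.
    Deterministic in (signature, profile, seed).
    """
    if fs_hz < 200:
        raise InvalidProfileError(f"fs_hz must be >= 200, got {fs_hz}")
    rng = np.random.default_rng([seed, sig.seed, TASK_INDEX[profile.task_id]])

    duration = profile.duration_s
    completed = True
    if profile.completion_prob < 1.0 and rng.random() >= profile.completion_prob:
        completed = False
        duration *= rng.uniform(0.4, 1.0)
    n = int(round(duration * fs_hz))
    if n <= 0:
        raise InvalidProfileError("requested duration yields zero samples")

    t = np.arange(n) / fs_hz
    powerline_phase = rng.uniform(0, 2 * np.pi)
    powerline = powerline_amp * np.sin(2 * np.pi * 50.0 * t + powerline_phase)

    data = np.empty((len(CHANNELS), n))
    for ci, ch in enumerate(CHANNELS):
        region = CHANNEL_REGION[ch]
        x = np.zeros(n)
        for band in BANDS:
            lo, hi = _alpha_edges(sig.alpha_peak_hz) if band == "alpha" else BAND_EDGES[band]
            amp = sig.band_amplitudes[band] * sig.topography[region][band] * profile.band_factor(band)
            x += amp * _band_noise(rng, n, lo, hi, fs_hz)
        x += sig.noise_scale * _pink_noise(rng, n)
        x += powerline
        x += rng.uniform(-30.0, 30.0)  # DC offset, removed by the high-pass stage
        x += 8.0 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
        data[ci] = x

    return Recording(
        subject_id=sig.subject_id,
        task_id=profile.task_id,
        channel_labels=list(CHANNELS),
        fs_hz=fs_hz,
        data=data,
        meta={
            "seed": seed,
            "completed": completed,
            "nominal_duration_s": profile.duration_s,
            "alpha_peak_hz": sig.alpha_peak_hz,
        },
    )


def simulate_session(
    sig: SubjectSignature,
    profiles: list[TaskLoadProfile],
    seed: int = 0,
    fs_hz: float = 1000.0,
    powerline_amp: float = 2.0,
) -> list[Recording]:
    """One recording per task for a single subject.

    ``profiles`` must cover the four tasks exactly once each.
    """
    task_ids = [p.task_id for p in profiles]
    if len(set(task_ids)) != len(task_ids):
        raise InvalidProtocolError(f"duplicate task_ids in session protocol: {task_ids}")
    if set(task_ids) != set(TASKS):
        raise InvalidProtocolError(f"session must cover tasks {TASKS}, got {task_ids}")
    return [
        simulate_recording(sig, p, fs_hz=fs_hz, powerline_amp=powerline_amp, seed=seed)
        for p in profiles
    ]


def simulate_cohort_sessions(
    signatures: list[SubjectSignature],
    profiles: list[TaskLoadProfile] | None = None,
    seed: int = 0,
    fs_hz: float = 1000.0,
    powerline_amp: float = 2.0,
) -> list[Recording]:
    """Convenience: a full cohort's recordings, flattened (subject-major)."""
    profiles = profiles if profiles is not None else default_profiles()
    out: list[Recording] = []
    for sig in signatures:
        out.extend(simulate_session(sig, profiles, seed=seed, fs_hz=fs_hz, powerline_amp=powerline_amp))
    return out


def signature_to_dict(sig: SubjectSignature) -> dict:
    return dataclasses.asdict(sig)


def signature_from_dict(d: dict) -> SubjectSignature:
    return SubjectSignature(**d)
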