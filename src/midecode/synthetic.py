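"""Synthetic motor-imagery EEG with class-dependent ERD and domain shift.

The signal model is deliberately minimal: per channel, µ and β band
sinusoids whose amplitude is attenuated by a class x channel ERD depth
matrix (ramped on over the trial onset), plus 1/f background noise.  A
:class:`DomainShift` rescales amplitudes, jitters peak frequencies and
rescales the noise to emulate session- or subject-level covariate shift.

Negative ERD depths model ERS (amplification); the default profile uses
textbook lateralization (left hand -> C4, right hand -> C3, feet/tongue ->
Cz at distinct depths) so the four classes are geometrically separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    CANONICAL_CHANNELS,
    CLASS_NAMES,
    DEFAULT_FS,
    TRIAL_SAMPLES,
    Recording,
    TrialSet,
)

MU_BAND = (8.0, 13.0)
BETA_BAND = (17.0, 30.0)

__all__ = [
    "MU_BAND",
    "BETA_BAND",
    "SubjectProfile",
    "DomainShift",
    "SessionSchedule",
    "default_erd_depth",
    "generate_trial",
    "generate_session",
    "generate_multisession",
    "generate_subjects",
    "session_to_recording",
]


def default_erd_depth() -> np.ndarray:
    """Class x channel ERD attenuation fractions (rows follow CLASS_NAMES,
    columns follow C3, Cz, C4)."""
    return np.array(
        [
            [0.10, 0.15, 0.70],  # left hand  -> contralateral C4
            [0.70, 0.15, 0.10],  # right hand -> contralateral C3
            [0.10, 0.70, 0.10],  # feet       -> Cz, deep
            [0.25, 0.40, 0.25],  # tongue     -> Cz, shallower + bilateral
        ]
    )


@dataclass
class SubjectProfile:
    """Stationary per-subject generation parameters."""

    mu_amp: np.ndarray = field(default_factory=lambda: np.full(3, 10.0))  # µV per channel
    beta_amp: np.ndarray = field(default_factory=lambda: np.full(3, 5.0))
    mu_freq: float = 11.0  # Hz, inside the µ band
    beta_freq: float = 22.0  # Hz, inside the β band
    noise_scale: float = 10.0  # 1/f background RMS, µV
    erd_depth: np.ndarray = field(default_factory=default_erd_depth)
    rng_seed: int = 0

    def __post_init__(self):
        self.mu_amp = np.asarray(self.mu_amp, dtype=np.float64)
        self.beta_amp = np.asarray(self.beta_amp, dtype=np.float64)
        self.erd_depth = np.asarray(self.erd_depth, dtype=np.float64)
        if np.any(self.mu_amp < 0) or np.any(self.beta_amp < 0) or self.noise_scale < 0:
            raise ValueError("amplitudes must be non-negative")
        if np.any(self.erd_depth > 1):
            raise ValueError("erd_depth entries must be <= 1 (negative = ERS)")
        if not MU_BAND[0] <= self.mu_freq <= MU_BAND[1]:
            raise ValueError(f"mu_freq {self.mu_freq} outside µ band {MU_BAND}")
        if not BETA_BAND[0] <= self.beta_freq <= BETA_BAND[1]:
            raise ValueError(f"beta_freq {self.beta_freq} outside β band {BETA_BAND}")
        if self.erd_depth.shape != (len(CLASS_NAMES), len(CANONICAL_CHANNELS)):
            raise ValueError("erd_depth must be 4 classes x 3 channels")


@dataclass
class DomainShift:
    """Multiplicative / additive covariate shift applied to one session."""

    amp_scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    freq_jitter: float = 0.0  # Hz added to both peak frequencies
    noise_gain: float = 1.0

    def __post_init__(self):
        self.amp_scale = np.broadcast_to(
            np.asarray(self.amp_scale, dtype=np.float64), (3,)
        ).copy()
        if np.any(self.amp_scale <= 0) or self.noise_gain < 0:
            raise ValueError("amp_scale must be positive, noise_gain non-negative")

    @classmethod
    def identity(cls) -> "DomainShift":
        return cls()


@dataclass
class SessionSchedule:
    """Run/trial layout of one recording session."""

    n_runs: int = 6
    per_class_per_run: int = 12
    classes: tuple[str, ...] = CLASS_NAMES

    @property
    def trials_per_run(self) -> int:
        return self.per_class_per_run * len(self.classes)

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


def _onset_envelope(n: int, fs: float, ramp_s: float = 0.25) -> np.ndarray:
    """Raised-cosine ramp 0 -> 1 over ``ramp_s`` seconds, then hold at 1."""
    env = np.ones(n)
    k = int(round(ramp_s * fs))
    if k > 0:
        t = np.arange(min(k, n))
        env[: len(t)] = 0.5 * (1.0 - np.cos(np.pi * t / k))
    return env


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise by spectral shaping of white noise (exponent 1)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def generate_trial(
    profile: SubjectProfile,
    label: int | str,
    shift: DomainShift,
    rng: np.random.Generator,
    fs: float = DEFAULT_FS,
    n_samples: int = TRIAL_SAMPLES,
    ramp_s: float = 0.25,
) -> np.ndarray:
    """One 2-s, 3-channel trial (3 x 500 at 250 Hz) for the given class.

    Per channel c:  A_mu,c (1 - d[label,c] env(t)) sin(2π f_mu t + φ)
                  + A_beta,c (1 - d[label,c] env(t)) sin(2π f_beta t + φ')
                  + noise_scale * 1/f noise,
    with the domain shift applied to amplitudes, frequencies and noise.
    """
    if isinstance(label, str):
        if label not in CLASS_NAMES:
            raise KeyError(f"unknown class label: {label!r}")
        label = CLASS_NAMES.index(label)
    if not 0 <= label < len(CLASS_NAMES):
        raise KeyError(f"unknown class label index: {label}")
    t = np.arange(n_samples) / fs
    env = _onset_envelope(n_samples, fs, ramp_s)
    f_mu = profile.mu_freq + shift.freq_jitter
    f_beta = profile.beta_freq + shift.freq_jitter
    if not MU_BAND[0] <= f_mu <= MU_BAND[1]:
        raise ValueError(f"shifted µ peak {f_mu} Hz leaves the µ band {MU_BAND}")
    if not BETA_BAND[0] <= f_beta <= BETA_BAND[1]:
        raise ValueError(f"shifted β peak {f_beta} Hz leaves the β band {BETA_BAND}")
    trial = np.empty((3, n_samples))
    for c in range(3):
        depth = profile.erd_depth[label, c]
        attn = 1.0 - depth * env
        phi_mu, phi_beta = rng.uniform(0, 2 * np.pi, size=2)
        a_mu = profile.mu_amp[c] * shift.amp_scale[c]
        a_beta = profile.beta_amp[c] * shift.amp_scale[c]
        sig = a_mu * attn * np.sin(2 * np.pi * f_mu * t + phi_mu)
        sig = sig + a_beta * attn * np.sin(2 * np.pi * f_beta * t + phi_beta)
        noise_rms = profile.noise_scale * shift.noise_gain
        if noise_rms > 0:
            sig = sig + noise_rms * _pink_noise(n_samples, rng)
        trial[c] = sig
    return trial


def generate_session(
    profile: SubjectProfile,
    schedule: SessionSchedule | None = None,
    shift: DomainShift | None = None,
    rng: np.random.Generator | None = None,
    domain_id: int = 0,
    subject_id: int = 0,
) -> TrialSet:
    """Generate one session: runs in order, classes shuffled within each run
    with exact per-run class balance.  Deterministic under a fixed rng seed."""
    schedule = schedule or SessionSchedule()
    shift = shift or DomainShift.identity()
    rng = rng or np.random.default_rng(profile.rng_seed)
    trials, labels, runs = [], [], []
    class_idx = [CLASS_NAMES.index(c) for c in schedule.classes]
    for run in range(schedule.n_runs):
        order = np.repeat(class_idx, schedule.per_class_per_run)
        rng.shuffle(order)
        for label in order:
            trials.append(generate_trial(profile, int(label), shift, rng))
            labels.append(int(label))
            runs.append(run)
    n = len(trials)
    return TrialSet(
        trials=np.asarray(trials),
        labels=np.asarray(labels),
        domain_ids=np.full(n, domain_id, dtype=np.int64),
        runs=np.asarray(runs),
        fs=DEFAULT_FS,
        meta={"subject_id": subject_id, "session_id": domain_id},
    )


def generate_multisession(
    profile: SubjectProfile,
    n_sessions: int,
    shifts: list[DomainShift],
    rng: np.random.Generator | None = None,
    schedule: SessionSchedule | None = None,
    subject_id: int = 0,
    domain_id_offset: int = 0,
) -> list[TrialSet]:
    """Sessions sharing one subject profile but each with its own shift and a
    distinct session-domain id."""
    if n_sessions != len(shifts):
        raise ValueError(f"n_sessions={n_sessions} but {len(shifts)} shifts given")
    rng = rng or np.random.default_rng(profile.rng_seed)
    return [
        generate_session(
            profile,
            schedule=schedule,
            shift=shifts[s],
            rng=rng,
            domain_id=domain_id_offset + s,
            subject_id=subject_id,
        )
        for s in range(n_sessions)
    ]


def generate_subjects(
    n_subjects: int,
    seed: int = 0,
    schedule: SessionSchedule | None = None,
    base_profile: SubjectProfile | None = None,
    shift_spread: float = 0.25,
) -> list[TrialSet]:
    """One session per subject with subject-level covariate shift; domain ids
    are subject indices (for leave-one-subject-out experiments)."""
    rng = np.random.default_rng(seed)
    base = base_profile or SubjectProfile()
    out = []
    for s in range(n_subjects):
        shift = DomainShift(
            amp_scale=np.exp(rng.uniform(-shift_spread, shift_spread, size=3)),
            freq_jitter=float(rng.uniform(-1.0, 1.0)),
            noise_gain=float(np.exp(rng.uniform(-shift_spread, shift_spread))),
        )
        out.append(
            generate_session(
                base, schedule=schedule, shift=shift, rng=rng, domain_id=s, subject_id=s
            )
        )
    return out


def session_to_recording(
    session: TrialSet, gap_samples: int = 250, offset_s: float = 0.0
) -> Recording:
    """Concatenate a session's trials into a continuous recording with
    inter-trial gaps and event markers (for exercising ``epoch``)."""
    n, _, L = session.trials.shape
    step = L + gap_samples
    data = np.zeros((3, n * step + gap_samples))
    events = []
    for k in range(n):
        start = gap_samples + k * step
        data[:, start : start + L] = session.trials[k]
        events.append((start - int(round(offset_s * session.fs)), int(session.labels[k])))
    return Recording(
        data=data,
        fs=session.fs,
        channel_names=CANONICAL_CHANNELS,
        events=events,
        meta=dict(session.meta) | {"domain_id": int(session.domain_ids[0]) if n else 0},
    )
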