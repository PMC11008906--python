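"""Age-structured synthetic single-lead ECG cohorts.

Each heartbeat is a sum of five Gaussian deflections (P, Q, R, S, T) with
per-age-group amplitudes, widths and centre offsets relative to the R peak.
Beat-to-beat timing comes from an NN-interval model with respiratory sinus
arrhythmia (a sinusoid at the breathing frequency), sign-alternating
fragmentation perturbations, and a slow sinusoidal drift.  R-peak amplitude
is additionally modulated at the breathing frequency so that ECG-derived
respiration is recoverable.  White Gaussian measurement noise is added last.

The default profile injects the age trends the downstream explainability
stages are expected to recover: breathing rate declines monotonically with
age, P-wave amplitude rises up to the 55-59 group and declines afterwards,
respiratory sinus arrhythmia shrinks while fragmentation grows (driving
pNN20 down and PAS up), T-wave amplitude declines, and mean heart rate
drifts slightly upwards.

Ground-truth annotations (R-peak samples, fiducial points, NN series) are
attached to every synthetic record under ``EcgRecord.truth``; they exist
for tests and benchmarks only and are never consumed by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .age_groups import N_AGE_GROUPS
from .records import EcgRecord

WAVE_NAMES = ("P", "Q", "R", "S", "T")

#: amplitude fraction defining wave onset/offset (a Gaussian falls to 10 %
#: of its peak at centre ± sqrt(2 ln 10) sigma)
ONSET_FRACTION = 0.1
_ONSET_SIGMA = float(np.sqrt(2.0 * np.log(1.0 / ONSET_FRACTION)))


@dataclass
class WaveShape:
    """One Gaussian deflection: amplitude (mV), width sigma (ms), centre (ms rel. R)."""

    amplitude_mv: float
    width_ms: float
    center_ms: float

    def validate(self) -> None:
        if not np.isfinite(self.amplitude_mv):
            raise ValueError("wave amplitude must be finite")
        if not self.width_ms > 0:
            raise ValueError("wave width must be positive")


@dataclass
class GroupProfile:
    """Morphology and rhythm parameters for one age group."""

    waves: dict  # name -> WaveShape
    mean_hr_bpm: float = 65.0
    breathing_rate_bpm: float = 14.0
    rsa_depth_ms: float = 30.0
    fragmentation: float = 0.1
    drift_amplitude_ms: float = 20.0
    drift_period_s: float = 60.0
    resp_amp_mod: float = 0.08  # relative R-amplitude modulation depth

    def validate(self) -> None:
        if set(self.waves) != set(WAVE_NAMES):
            raise ValueError(f"waves must be exactly {WAVE_NAMES}")
        for w in self.waves.values():
            w.validate()
        if not 30.0 <= self.mean_hr_bpm <= 180.0:
            raise ValueError("mean heart rate must lie in [30, 180] bpm")
        if not 4.0 <= self.breathing_rate_bpm <= 40.0:
            raise ValueError("breathing rate must lie in [4, 40] breaths/min")
        if not 0.0 <= self.fragmentation <= 1.0:
            raise ValueError("fragmentation must lie in [0, 1]")
        if self.drift_period_s <= 0:
            raise ValueError("drift period must be positive")


@dataclass
class AgeEffectProfile:
    """Per-age-group parameters; exactly one entry per ordinal group."""

    groups: dict  # group index -> GroupProfile

    def validate(self) -> None:
        if sorted(self.groups) != list(range(N_AGE_GROUPS)):
            raise ValueError(f"profile must define all {N_AGE_GROUPS} age groups")
        for g in self.groups.values():
            g.validate()

    def __getitem__(self, group: int) -> GroupProfile:
        return self.groups[group]


@dataclass
class SyntheticCohortConfig:
    """Cohort-level generation settings.

    Subject-level jitter scales are deliberately small relative to the
    between-group steps of the default profile: the cohort is a test
    harness whose group structure is separable by construction.
    """

    subjects_per_group: int = 10
    duration_s: float = 300.0
    fs: float = 100.0
    noise_std_mv: float = 0.02
    seed: int = 0
    profile: AgeEffectProfile | None = None
    groups: list | None = None  # subset of group indices; None = all 15
    amplitude_jitter_rel: float = 0.04
    hr_jitter_bpm: float = 1.5
    breathing_jitter_bpm: float = 0.2
    fragmentation_delta_ms: float = 8.0

    def validate(self) -> None:
        if self.subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.duration_s < 60.0:
            raise ValueError("record duration must be at least 60 s")
        if self.fs not in (100.0, 1000.0, 100, 1000):
            raise ValueError("sampling rate must be 100 or 1000 Hz")
        if self.noise_std_mv < 0:
            raise ValueError("noise std must be non-negative")
        if self.profile is not None:
            self.profile.validate()

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def _default_waves(p_amp: float, t_amp: float) -> dict:
    return {
        "P": WaveShape(p_amp, 18.0, -160.0),
        "Q": WaveShape(-0.15, 8.0, -25.0),
        "R": WaveShape(1.0, 9.0, 0.0),
        "S": WaveShape(-0.25, 8.0, 25.0),
        "T": WaveShape(t_amp, 30.0, 220.0),
    }


def _p_amp_rise_fall(g: int) -> float:
    # rises to a maximum at the 55-59y group (index 8), declines afterwards
    return 0.10 + 0.02 * g if g <= 8 else 0.26 - 0.03 * (g - 8)


def default_age_profile() -> AgeEffectProfile:
    """The standard cohort: all injected age trends active."""
    groups = {}
    for g in range(N_AGE_GROUPS):
        groups[g] = GroupProfile(
            waves=_default_waves(p_amp=_p_amp_rise_fall(g), t_amp=0.35 - 0.015 * g),
            mean_hr_bpm=62.0 + 0.8 * g,
            breathing_rate_bpm=16.5 - 0.55 * g,
            rsa_depth_ms=45.0 - 2.5 * g,
            fragmentation=0.02 + 0.05 * g,
        )
    return AgeEffectProfile(groups)


def two_effect_profile() -> AgeEffectProfile:
    """Only breathing-rate decline and P-amplitude rise-then-fall vary with age."""
    groups = {}
    for g in range(N_AGE_GROUPS):
        groups[g] = GroupProfile(
            waves=_default_waves(p_amp=_p_amp_rise_fall(g), t_amp=0.30),
            mean_hr_bpm=65.0,
            breathing_rate_bpm=16.5 - 0.55 * g,
            rsa_depth_ms=25.0,
            fragmentation=0.1,
        )
    return AgeEffectProfile(groups)


def flat_age_profile() -> AgeEffectProfile:
    """Null cohort: every group has identical parameters (chance-level task)."""
    groups = {
        g: GroupProfile(
            waves=_default_waves(p_amp=0.18, t_amp=0.28),
            mean_hr_bpm=67.0,
            breathing_rate_bpm=13.0,
            rsa_depth_ms=28.0,
            fragmentation=0.3,
        )
        for g in range(N_AGE_GROUPS)
    }
    return AgeEffectProfile(groups)


def p_amplitude_only_profile(low: float = 0.08, high: float = 0.22) -> AgeEffectProfile:
    """Only P-wave amplitude varies (linearly in group index); all else flat.

    The T amplitude is fixed well above both P levels so that a
    translation-tolerant amplitude detector cannot confuse the P and T
    bumps: the only discriminative cue is the P wave itself.
    """
    groups = {}
    for g in range(N_AGE_GROUPS):
        p_amp = low + (high - low) * g / (N_AGE_GROUPS - 1)
        groups[g] = GroupProfile(
            waves=_default_waves(p_amp=p_amp, t_amp=0.45),
            mean_hr_bpm=67.0,
            breathing_rate_bpm=13.0,
            rsa_depth_ms=28.0,
            fragmentation=0.3,
        )
    return AgeEffectProfile(groups)


def make_beat_template(waves: dict, fs: float, beat_len: int) -> np.ndarray:
    """Evaluate the Gaussian-sum beat on ``beat_len`` samples, R at the centre.

    Raises ``ValueError`` for non-positive widths or if the window does not
    span every wave centre ± 3 widths.
    """
    for w in waves.values():
        if not w.width_ms > 0:
            raise ValueError("wave width must be positive")
    r_index = beat_len // 2
    t_ms = (np.arange(beat_len) - r_index) / fs * 1000.0
    half_span_ms = min(r_index, beat_len - 1 - r_index) / fs * 1000.0
    for w in waves.values():
        if abs(w.center_ms) + 3 * w.width_ms > half_span_ms + 1e-9:
            raise ValueError("beat_len does not span all wave centers ± 3 widths")
    out = np.zeros(beat_len)
    for w in waves.values():
        out += w.amplitude_mv * np.exp(-0.5 * ((t_ms - w.center_ms) / w.width_ms) ** 2)
    return out


def _gaussian_sum(t_ms: np.ndarray, waves: dict, r_amp_scale: float = 1.0) -> np.ndarray:
    out = np.zeros_like(t_ms)
    for name, w in waves.items():
        amp = w.amplitude_mv * (r_amp_scale if name == "R" else 1.0)
        out += amp * np.exp(-0.5 * ((t_ms - w.center_ms) / w.width_ms) ** 2)
    return out


def simulate_nn_series(
    mean_hr: float,
    rsa_depth: float,
    breathing_rate: float,
    fragmentation: float,
    drift_amplitude: float,
    drift_period: float,
    n_beats: int,
    seed: int,
    fragmentation_delta_ms: float = 8.0,
) -> np.ndarray:
    """Generate ``n_beats`` NN intervals in ms.

    NN_i = base + RSA sinusoid at the breathing frequency + slow drift
    sinusoid + sign-alternating fragmentation perturbations (applied with
    probability ``fragmentation`` per beat).
    """
    if not 30.0 <= mean_hr <= 180.0:
        raise ValueError("mean heart rate must lie in [30, 180] bpm")
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    rng = np.random.default_rng(seed)
    base = 60000.0 / mean_hr
    f_b = breathing_rate / 60.0
    apply = rng.random(n_beats) < fragmentation
    signs = (-1.0) ** np.arange(n_beats)
    nn = np.empty(n_beats)
    t = 0.0  # seconds, time of the interval's start beat
    for i in range(n_beats):
        v = base
        if rsa_depth != 0.0:
            v += rsa_depth * np.sin(2.0 * np.pi * f_b * t)
        if drift_amplitude != 0.0:
            v += drift_amplitude * np.sin(2.0 * np.pi * t / drift_period)
        if apply[i]:
            v += fragmentation_delta_ms * signs[i]
        nn[i] = v
        t += v / 1000.0
    return nn


def synthesize_record(
    age_group: int,
    profile: AgeEffectProfile,
    config: SyntheticCohortConfig,
    seed: int,
    subject_id: str | None = None,
) -> EcgRecord:
    """Render one subject's record: beat templates at cumulative NN positions
    plus white noise, with ground-truth annotations attached."""
    profile.validate()
    config.validate()
    if age_group not in profile.groups:
        raise ValueError(f"age group {age_group} not present in profile")
    gp = profile[age_group]
    rng = np.random.default_rng(seed)

    # subject-level parameter jitter around the group profile
    waves = {}
    for name, w in gp.waves.items():
        amp = w.amplitude_mv * (1.0 + config.amplitude_jitter_rel * rng.standard_normal())
        waves[name] = WaveShape(amp, w.width_ms, w.center_ms)
    hr = float(np.clip(gp.mean_hr_bpm + config.hr_jitter_bpm * rng.standard_normal(), 30.0, 180.0))
    br = float(np.clip(gp.breathing_rate_bpm + config.breathing_jitter_bpm * rng.standard_normal(), 4.0, 40.0))

    base_nn_s = 60.0 / hr
    if config.duration_s < 2.0 * base_nn_s:
        raise ValueError("record duration too short for two beats")
    n_beats = int(np.ceil(config.duration_s / base_nn_s)) + 8
    nn_ms = simulate_nn_series(
        hr, gp.rsa_depth_ms, br, gp.fragmentation,
        gp.drift_amplitude_ms, gp.drift_period_s, n_beats,
        seed=int(rng.integers(2**31 - 1)),
        fragmentation_delta_ms=config.fragmentation_delta_ms,
    )
    r_times = 0.5 + np.cumsum(np.concatenate([[0.0], nn_ms[:-1]])) / 1000.0
    # keep beats whose full template fits inside the record
    margin = 0.45
    keep = (r_times > margin) & (r_times < config.duration_s - margin)
    r_times = r_times[keep]

    fs = float(config.fs)
    n_samples = int(round(config.duration_s * fs))
    signal = np.zeros(n_samples)
    f_b = br / 60.0
    half_window = int(round(0.45 * fs))
    for r_t in r_times:
        r_amp_scale = 1.0 + gp.resp_amp_mod * np.sin(2.0 * np.pi * f_b * r_t)
        centre = int(round(r_t * fs))
        lo = max(0, centre - half_window)
        hi = min(n_samples, centre + half_window + 1)
        t_ms = (np.arange(lo, hi) / fs - r_t) * 1000.0
        signal[lo:hi] += _gaussian_sum(t_ms, waves, r_amp_scale)
    if config.noise_std_mv > 0:
        signal += config.noise_std_mv * rng.standard_normal(n_samples)

    truth = {
        "r_times_s": r_times,
        "r_samples": np.round(r_times * fs).astype(int),
        "nn_ms": np.diff(r_times) * 1000.0,
        "fiducials_ms": _truth_fiducials(waves),
        "waves": {k: (w.amplitude_mv, w.width_ms, w.center_ms) for k, w in waves.items()},
        "breathing_rate_bpm": br,
        "mean_hr_bpm": hr,
    }
    return EcgRecord(
        subject_id=subject_id or f"g{age_group:02d}s{seed}",
        fs=fs,
        signal=signal,
        age_group=age_group,
        truth=truth,
    )


def _truth_fiducials(waves: dict) -> dict:
    """Analytic fiducial positions (ms relative to R) of the Gaussian beat."""
    fid = {}
    for name in ("P", "T"):
        w = waves[name]
        fid[f"{name}_onset"] = w.center_ms - _ONSET_SIGMA * w.width_ms
        fid[f"{name}_peak"] = w.center_ms
        fid[f"{name}_offset"] = w.center_ms + _ONSET_SIGMA * w.width_ms
    for name in ("Q", "R", "S"):
        fid[name] = waves[name].center_ms
    return fid


def generate_cohort(config: SyntheticCohortConfig) -> list:
    """Generate the full cohort: ``subjects_per_group`` records per age group."""
    config.validate()
    profile = config.profile or default_age_profile()
    profile.validate()
    group_list = config.groups if config.groups is not None else list(range(N_AGE_GROUPS))
    if config.groups is not None:
        bad = [g for g in group_list if g not in profile.groups]
        if bad:
            raise ValueError(f"groups {bad} not present in profile")
    ss = np.random.SeedSequence(config.seed)
    records = []
    for g in group_list:
        for s in range(config.subjects_per_group):
            child = ss.spawn(1)[0]
            seed = int(child.generate_state(1)[0] % (2**31 - 1))
            rec = synthesize_record(
                g, profile, config, seed, subject_id=f"g{g:02d}s{s:03d}"
            )
            records.append(rec)
    return records
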