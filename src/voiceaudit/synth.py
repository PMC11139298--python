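"""Synthetic voice cohort generator.

Generates a matched patient/control cohort of synthetic voice recordings with
known ground-truth pathology parameters and controllable recording biases, so
the downstream analysis stack (feature extraction, redundancy removal, model
evaluation, explainability, bias audit) can be exercised end to end without any
clinical data.

The generator emulates the statistical structure of a unilateral vocal fold
paralysis (UVFP) screening dataset:

* patients and controls matched pairwise on sex, smoking status and age
  (within three years);
* three sustained /a/ vowel recordings and three reading segments per
  participant (the reading segments are thirds of one longer passage, and the
  un-split passage is what clinician raters hear);
* pathology expressed as raised jitter/shimmer, lowered harmonics-to-noise
  ratio, shifted fundamental frequency and a weaker intrinsic voice level;
* two injectable recording biases: a *duration* bias (control recordings
  cropped to fixed lengths, patient lengths variable) and a *gain* bias
  (patient recordings amplified with a correspondingly raised noise floor).

Audio is produced by a source-filter scheme: a quasi-periodic glottal impulse
train with cycle-to-cycle period (jitter) and amplitude (shimmer) perturbation,
smoothed by two one-pole low-pass stages, mixed with aspiration noise scaled to
a target harmonics-to-noise ratio, and passed through a cascade of second-order
formant resonators.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

SAMPLE_RATE = 16_000

#: Textbook formant frequencies/bandwidths (Hz) for a sustained /a/.
VOWEL_A_FORMANTS = ((700.0, 130.0), (1220.0, 70.0), (2600.0, 160.0))

#: Alternating vowel targets cycled through by the reading proxy.
READING_FORMANT_TARGETS = (
    VOWEL_A_FORMANTS,
    ((300.0, 90.0), (2300.0, 120.0), (3000.0, 200.0)),   # /i/-like
    ((450.0, 100.0), (800.0, 80.0), (2830.0, 180.0)),    # /u/-like
    ((530.0, 90.0), (1840.0, 100.0), (2480.0, 180.0)),   # /e/-like
)


# ---------------------------------------------------------------------------
# Specification dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathologyEffects:
    """Additive pathology shifts applied to patient baselines.

    delta_jitter / delta_shimmer are in percentage points of period/amplitude
    perturbation, delta_hnr in dB (negative = breathier), delta_f0 in
    semitones, intrinsic_intensity in dB (negative = weaker voice).
    """

    delta_jitter: float = 0.0
    delta_shimmer: float = 0.0
    delta_hnr: float = 0.0
    delta_f0: float = 0.0
    intrinsic_intensity: float = 0.0
    #: extra pause fraction in connected speech (air escape shortens phrases)
    delta_pause: float = 0.0
    #: relative formant-bandwidth broadening (glottal damping)
    delta_formant_bw: float = 0.0

    def any_active(self) -> bool:
        return any(v != 0.0 for v in asdict(self).values())


@dataclass(frozen=True)
class BiasSwitches:
    """Recording-channel biases injected at generation time.

    With ``duration_bias`` on, control recordings are cropped to the fixed
    durations below while patient durations vary (reading segments lognormal,
    vowels normally distributed). With ``gain_bias`` on, patient recordings
    get *compensatory* microphone gain — the weaker the voice, the more the
    gain is raised toward (and slightly past) a target level, plus a random
    offset — and the noise floor rises by the same amount (amplification
    raises room noise too). Compensation makes the recorded level stop
    tracking, and mildly invert, the true voice weakness: the signature bias
    of the audited setting.
    """

    duration_bias: bool = False
    control_reading_duration: float = 3.5
    control_vowel_duration: float = 4.11
    patient_reading_lognorm: tuple[float, float] = (np.log(8.0), 0.55)
    patient_reading_cap: float = 30.0
    #: fraction of patient reading passages that received the same fixed
    #: cropping as controls at storage time (duration does not separate
    #: those recordings, keeping the duration probe below perfection)
    patient_cropped_fraction: float = 0.3
    #: extra cropping probability for mild cases (severity < 0.6): in the
    #: emulated dataset the patients every channel misses are largely the
    #: same ones, so mildness and fixed duration co-occur
    patient_crop_mild_boost: float = 0.75
    patient_vowel_mean: float = 3.74
    patient_vowel_sd: float = 1.3
    gain_bias: bool = False
    gain_target_db: float = -25.0        # level the operator aims for
    gain_compensation: float = 1.0       # weak voices boosted to the target
    gain_offset_db: tuple[float, float] = (0.7, 1.0)   # (mean, sd) extra gain
    patient_gain_db: tuple[float, float] = (0.0, 12.0)  # clip range
    base_noise_floor_db: float = -55.0
    noise_floor_sd: float = 4.0          # between-session room/mic variation
    noise_tracks_gain: bool = True


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort; seed determines everything."""

    n_per_group: int = 77
    age_range: tuple[float, float] = (18.0, 90.0)
    pathology: PathologyEffects = field(default_factory=PathologyEffects)
    biases: BiasSwitches = field(default_factory=BiasSwitches)
    sample_rate: int = SAMPLE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        b = self.biases
        for name in ("control_reading_duration", "control_vowel_duration",
                     "patient_reading_cap", "patient_vowel_mean"):
            if getattr(b, name) <= 0:
                raise ValueError(f"invalid duration parameter: {name}")
        if b.patient_reading_lognorm[1] < 0 or b.patient_vowel_sd < 0:
            raise ValueError("invalid distribution scale in bias_switches")
        if b.patient_gain_db[0] > b.patient_gain_db[1]:
            raise ValueError("invalid patient_gain_db range")
        if self.sample_rate <= 0:
            raise ValueError("invalid sample_rate")

    # -- standard study conditions -------------------------------------
    @staticmethod
    def default_effects() -> PathologyEffects:
        """Mean pathology shifts for the emulated cohort.

        Magnitudes are calibrated, together with the per-participant
        severity spread, so the cohort reproduces the separability the
        emulated study reports: a multi-feature classifier reaches a median
        ROC AUC in the high .80s while no single acoustic feature exceeds
        the low .70s.
        """
        return PathologyEffects(delta_jitter=0.8, delta_shimmer=1.8,
                                delta_hnr=-3.0, delta_f0=-2.5,
                                intrinsic_intensity=-3.0,
                                delta_pause=0.05, delta_formant_bw=1.1)

    @classmethod
    def default_biased(cls, n_per_group: int = 77, seed: int = 0) -> "CohortSpec":
        """Pathology AND both recording biases on: the emulated study dataset."""
        return cls(n_per_group=n_per_group, seed=seed,
                   pathology=cls.default_effects(),
                   biases=BiasSwitches(duration_bias=True, gain_bias=True))

    @classmethod
    def bias_only(cls, n_per_group: int = 77, seed: int = 0) -> "CohortSpec":
        """Recording biases on, no pathology: labels carry no vocal signal."""
        return cls(n_per_group=n_per_group, seed=seed,
                   biases=BiasSwitches(duration_bias=True, gain_bias=True))

    @classmethod
    def pathology_only(cls, n_per_group: int = 77, seed: int = 0,
                       effects: PathologyEffects | None = None) -> "CohortSpec":
        """Pathology on, biases off: only voice-quality features carry signal."""
        return cls(n_per_group=n_per_group, seed=seed,
                   pathology=effects or cls.default_effects())

    @classmethod
    def null(cls, n_per_group: int = 77, seed: int = 0) -> "CohortSpec":
        """Everything off: group labels are exchangeable by construction."""
        return cls(n_per_group=n_per_group, seed=seed)


@dataclass(frozen=True)
class Participant:
    id: str
    group: str           # "UVFP" | "control"
    age: float
    sex: str             # "F" | "M"
    smoking: bool


@dataclass
class Recording:
    recording_id: str
    participant_id: str
    task: str            # "vowel" | "reading"
    segment_index: int   # 1..3
    waveform: np.ndarray
    sample_rate: int
    true_params: dict

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.sample_rate


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list[Participant]
    recordings: list[Recording]
    manifest: pd.DataFrame
    #: un-split reading passage per participant, used for clinician rating
    full_readings: dict[str, Recording] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Seeding scheme: one master seed, sub-streams by a stated counter key
# ---------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic sub-stream ``(seed, *key)`` of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _subseed(seed: int, *key: int) -> int:
    return int(_rng(seed, *key).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def glottal_pulse_train(f0: float, jitter: float, shimmer: float,
                        duration: float, sample_rate: int,
                        seed: int) -> np.ndarray:
    """Quasi-periodic impulse train with period/amplitude perturbation.

    ``jitter`` and ``shimmer`` are coefficients of variation in percent of the
    cycle period and pulse amplitude respectively (Gaussian, truncated at
    three standard deviations).
    """
    if not (60.0 <= f0 <= 400.0):
        raise ValueError(f"f0 {f0} Hz outside [60, 400]")
    if jitter < 0 or shimmer < 0:
        raise ValueError("jitter and shimmer must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    t0 = 1.0 / f0
    n = len(np.arange(0, duration, t0)) + 8
    eps = np.clip(rng.standard_normal(n), -3, 3)
    eta = np.clip(rng.standard_normal(n), -3, 3)
    periods = t0 * (1.0 + jitter / 100.0 * eps)
    times = np.concatenate([[0.0], np.cumsum(periods)])
    times = times[times < duration]
    amps = 1.0 + shimmer / 100.0 * eta[: len(times)]
    out = np.zeros(int(round(duration * sample_rate)))
    idx = np.minimum(np.round(times * sample_rate).astype(int), len(out) - 1)
    out[idx] += amps
    return out


def _formant_sos(formants, sample_rate: int) -> np.ndarray:
    """Second-order resonator cascade for the given (freq, bandwidth) pairs."""
    sos = []
    for freq, bw in formants:
        if bw <= 0:
            raise ValueError(f"unstable resonator: bandwidth {bw} <= 0")
        if freq <= 0 or freq >= sample_rate / 2:
            raise ValueError(f"formant frequency {freq} outside (0, Nyquist)")
        r = np.exp(-np.pi * bw / sample_rate)
        theta = 2 * np.pi * freq / sample_rate
        a1, a2 = -2 * r * np.cos(theta), r * r
        # unity gain at the resonance frequency
        w = np.exp(1j * theta)
        gain = abs(1.0 + a1 / w + a2 / w**2)
        sos.append([gain, 0.0, 0.0, 1.0, a1, a2])
    return np.asarray(sos)


def synthesize_phonation(f0: float, jitter: float, shimmer: float, hnr: float,
                         duration: float, sample_rate: int = SAMPLE_RATE,
                         formants=VOWEL_A_FORMANTS, seed: int = 0) -> np.ndarray:
    """Source-filter synthesis of a sustained phonation.

    A glottal impulse train (see :func:`glottal_pulse_train`) is smoothed by
    two one-pole low-pass stages (approximately -12 dB/octave spectral tilt),
    mixed with aspiration noise scaled post-filter so the harmonic-to-noise
    power ratio equals ``hnr`` dB, and filtered by the formant cascade.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pulses = glottal_pulse_train(f0, jitter, shimmer, duration, sample_rate,
                                 seed=int(rng.integers(2**31 - 1)))
    # glottal shaping: two one-pole low-pass stages
    src = sps.lfilter([1.0 - 0.96], [1.0, -0.96], pulses)
    src = sps.lfilter([1.0 - 0.96], [1.0, -0.96], src)
    sos = _formant_sos(formants, sample_rate)
    harmonic = sps.sosfilt(sos, src)
    noise = sps.sosfilt(sos, rng.standard_normal(len(pulses)))
    p_h = float(np.mean(harmonic**2))
    p_n = float(np.mean(noise**2))
    if p_n > 0 and p_h > 0:
        noise *= np.sqrt(p_h / (p_n * 10.0 ** (hnr / 10.0)))
    out = harmonic + noise
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


@dataclass(frozen=True)
class ReadingProfile:
    """Per-speaker parameters for the reading-passage proxy.

    Segment count scales with duration and the f0 declination is a rate per
    second, so the *local* statistics of the proxy (voiced-segment lengths,
    pitch slopes, pause structure) do not encode how long the recording is —
    only the duration itself does.
    """

    f0: float = 120.0
    jitter: float = 0.6
    shimmer: float = 4.0
    hnr: float = 22.0
    segments_per_second: float = 1.0
    n_segments_range: tuple[int, int] = (3, 60)
    pause_fraction: float = 0.18
    declination_st_per_s: float = 0.25
    f0_jitter_semitones: float = 1.5
    formant_bw_scale: float = 1.0


def synthesize_reading_proxy(profile: ReadingProfile, duration: float,
                             sample_rate: int = SAMPLE_RATE,
                             seed: int = 0) -> np.ndarray:
    """Connected-speech proxy: voiced segments with varying f0 and formant
    targets separated by silent gaps, totalling ``duration`` seconds.

    Not perceptually speech; it only reproduces the statistics the feature
    stack consumes (voiced/unvoiced alternation, f0 declination and movement,
    formant variety, pauses).
    """
    min_seg = 0.2
    if duration < min_seg:
        raise ValueError(f"duration {duration} s shorter than one segment")
    rng = np.random.default_rng(seed)
    lo, hi = profile.n_segments_range
    n_seg = int(np.clip(round(duration * profile.segments_per_second), lo, hi))
    n_seg = max(1, min(n_seg, int(duration // min_seg)))
    voiced_total = duration * (1.0 - profile.pause_fraction)
    weights = rng.uniform(0.6, 1.4, n_seg)
    seg_durs = np.maximum(voiced_total * weights / weights.sum(), min_seg)
    gap_total = max(duration - seg_durs.sum(), 0.0)
    if n_seg > 1 and profile.pause_fraction > 0:
        gw = rng.uniform(0.5, 1.5, n_seg - 1)
        gaps = gap_total * gw / gw.sum()
    else:
        gaps = np.zeros(max(n_seg - 1, 0))
    pieces = []
    elapsed = 0.0
    for i in range(n_seg):
        # declination resets every ~8 s, like breath groups in read speech
        semis = (-profile.declination_st_per_s * (elapsed % 8.0)
                 + rng.uniform(-1, 1) * profile.f0_jitter_semitones)
        elapsed += float(seg_durs[i]) + (float(gaps[i]) if i < len(gaps) else 0.0)
        f0 = float(np.clip(profile.f0 * 2.0 ** (semis / 12.0), 60.0, 400.0))
        formants = tuple(
            (f, b * profile.formant_bw_scale)
            for f, b in READING_FORMANT_TARGETS[i % len(READING_FORMANT_TARGETS)])
        pieces.append(synthesize_phonation(
            f0, profile.jitter, profile.shimmer, profile.hnr, float(seg_durs[i]),
            sample_rate, formants, seed=int(rng.integers(2**31 - 1))))
        if i < n_seg - 1 and len(gaps):
            pieces.append(np.zeros(int(round(gaps[i] * sample_rate))))
    out = np.concatenate(pieces)
    n_target = int(round(duration * sample_rate))
    if len(out) >= n_target:
        out = out[:n_target]
    else:
        out = np.pad(out, (0, n_target - len(out)))
    return out


def apply_recording_channel(waveform: np.ndarray, gain_db: float,
                            noise_floor_db: float, seed: int = 0
                            ) -> tuple[np.ndarray, bool]:
    """Microphone/channel simulation: gain, additive white noise floor, clipping.

    ``noise_floor_db`` is the RMS of the added noise in dB re full scale.
    Returns the processed waveform and a flag indicating whether clipping
    occurred.
    """
    w = np.asarray(waveform, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("waveform must be finite")
    rng = np.random.default_rng(seed)
    out = w * 10.0 ** (gain_db / 20.0)
    out = out + rng.standard_normal(len(w)) * 10.0 ** (noise_floor_db / 20.0)
    clipped = bool(np.any(np.abs(out) > 1.0))
    return np.clip(out, -1.0, 1.0), clipped


def rms_db(waveform: np.ndarray) -> float:
    """RMS level in dB re full scale (dBFS)."""
    p = float(np.mean(np.asarray(waveform, dtype=float) ** 2))
    return 10.0 * np.log10(max(p, 1e-20))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _participant_baselines(sex: str, rng: np.random.Generator) -> dict:
    """Group-shared baseline voice parameters for one participant."""
    if sex == "F":
        f0 = float(np.clip(rng.normal(205.0, 18.0), 140.0, 330.0))
    else:
        f0 = float(np.clip(rng.normal(118.0, 12.0), 75.0, 180.0))
    return {
        "f0": f0,
        "jitter": float(np.clip(rng.normal(0.6, 0.25), 0.15, 1.6)),
        "shimmer": float(np.clip(rng.normal(4.0, 1.2), 1.5, 8.0)),
        "hnr": float(np.clip(rng.normal(23.0, 3.0), 14.0, 31.0)),
        "level_db": float(np.clip(rng.normal(-26.0, 3.0), -35.0, -17.0)),
        "pause_add": 0.0,
        "bw_scale": float(np.clip(rng.normal(1.0, 0.08), 0.7, 1.3)),
    }


def _apply_pathology(base: dict, eff: PathologyEffects, severity: float,
                     rng: np.random.Generator) -> dict:
    """Additive pathology shifts with partially independent per-dimension
    severities: the clinical dimensions of a paralysis (perturbation,
    breathiness, pitch, loudness) co-vary but are not locked together."""
    def sev() -> float:
        return float(np.clip(0.45 * severity + rng.normal(0.0, 0.5) + 0.1,
                             0.05, 2.0))

    out = dict(base)
    out["jitter"] = max(base["jitter"] + sev() * eff.delta_jitter, 0.05)
    out["shimmer"] = max(base["shimmer"] + sev() * eff.delta_shimmer, 0.5)
    out["hnr"] = base["hnr"] + sev() * eff.delta_hnr
    out["f0"] = float(np.clip(
        base["f0"] * 2.0 ** (sev() * eff.delta_f0 / 12.0), 61.0, 395.0))
    out["level_db"] = base["level_db"] + sev() * eff.intrinsic_intensity
    out["pause_add"] = max(sev() * eff.delta_pause, 0.0)
    out["bw_scale"] = max(1.0 + sev() * eff.delta_formant_bw, 0.3)
    return out


def _recording_variation(voice: dict, rng: np.random.Generator) -> dict:
    """Session-to-session variation: every recording of a participant is a
    noisy realization of their underlying voice state."""
    return {
        "f0": float(np.clip(voice["f0"] * rng.normal(1.0, 0.04), 61.0, 395.0)),
        "jitter": float(max(voice["jitter"] * rng.normal(1.0, 0.12), 0.05)),
        "shimmer": float(max(voice["shimmer"] * rng.normal(1.0, 0.12), 0.5)),
        "hnr": float(voice["hnr"] + rng.normal(0.0, 1.5)),
        "level_db": float(voice["level_db"] + rng.normal(0.0, 2.0)),
        "pause_add": float(max(voice.get("pause_add", 0.0)
                               + rng.normal(0.0, 0.02), 0.0)),
        "bw_scale": float(np.clip(voice.get("bw_scale", 1.0)
                                  * rng.normal(1.0, 0.05), 0.3, 3.0)),
    }


def _scale_to_level(w: np.ndarray, level_db: float) -> np.ndarray:
    cur = rms_db(w)
    return w * 10.0 ** ((level_db - cur) / 20.0)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort: participants, recordings, manifest.

    Patients come first (ids ``p000``...), each followed by a control matched
    on sex and smoking status and within three years of age. Each participant
    gets 3 sustained-vowel recordings and one reading passage split in thirds
    (3 reading segments); the un-split passage is retained for clinician
    rating. Identical spec (including seed) reproduces the cohort exactly.
    """
    seed = spec.seed
    eff = spec.pathology
    b = spec.biases
    participants: list[Participant] = []
    recordings: list[Recording] = []
    full_readings: dict[str, Recording] = {}
    rows = []

    for i in range(spec.n_per_group):
        demo_rng = _rng(seed, 0, i)
        sex = "F" if i % 2 == 0 else "M"
        smoking = bool(demo_rng.uniform() < 0.25)
        lo, hi = spec.age_range
        age_p = float(np.round(demo_rng.uniform(lo, hi), 1))
        age_c = float(np.round(np.clip(age_p + demo_rng.uniform(-3, 3), lo, hi), 1))
        patient = Participant(f"p{i:03d}", "UVFP", age_p, sex, smoking)
        control = Participant(f"c{i:03d}", "control", age_c, sex, smoking)
        participants += [patient, control]

        for person, is_patient in ((patient, True), (control, False)):
            g = 1 if is_patient else 2
            prng = _rng(seed, g, i)
            base = _participant_baselines(sex, prng)
            if is_patient and eff.any_active():
                # wide severity spread: mild cases overlap with controls
                severity = float(prng.uniform(0.15, 1.45))
                voice = _apply_pathology(base, eff, severity, prng)
            else:
                severity = 0.0
                voice = dict(base)
            if b.gain_bias and is_patient:
                shortfall = b.gain_target_db - voice["level_db"]
                gain = float(np.clip(
                    b.gain_compensation * max(shortfall, 0.0)
                    + prng.normal(*b.gain_offset_db), *b.patient_gain_db))
            else:
                gain = 0.0
            noise_floor = float(
                prng.normal(b.base_noise_floor_db, b.noise_floor_sd)
                + (gain if b.noise_tracks_gain else 0.0))

            for task_code, task in ((0, "vowel"), (1, "reading")):
                n_seg = 3
                if task == "vowel":
                    segs = []
                    for s in range(n_seg):
                        srng = _rng(seed, g, i, task_code, s)
                        if b.duration_bias:
                            dur = (float(np.clip(srng.normal(
                                       b.patient_vowel_mean, b.patient_vowel_sd),
                                       1.0, 10.0))
                                   if is_patient else b.control_vowel_duration)
                        else:
                            dur = b.control_vowel_duration
                        segs.append((dur, srng))
                    for s, (dur, srng) in enumerate(segs):
                        tp = _recording_variation(voice, srng)
                        fmts = tuple((f, b * tp["bw_scale"])
                                     for f, b in VOWEL_A_FORMANTS)
                        w = synthesize_phonation(
                            tp["f0"], tp["jitter"], tp["shimmer"], tp["hnr"],
                            dur, spec.sample_rate, formants=fmts,
                            seed=_subseed(seed, g, i, task_code, s, 7))
                        w = _scale_to_level(w, tp["level_db"])
                        w, clipped = apply_recording_channel(
                            w, gain, noise_floor,
                            seed=_subseed(seed, g, i, task_code, s, 11))
                        rid = f"{person.id}_vowel_{s + 1}"
                        tp.update(gain=gain, noise_floor=noise_floor,
                                  clipped=clipped, severity=severity)
                        recordings.append(Recording(
                            rid, person.id, "vowel", s + 1, w,
                            spec.sample_rate, tp))
                else:
                    # one full passage, split in thirds
                    frng = _rng(seed, g, i, task_code)
                    if b.duration_bias:
                        crop_p = b.patient_cropped_fraction
                        if severity > 0:
                            crop_p += b.patient_crop_mild_boost * \
                                max(0.6 - severity, 0.0) / 0.6
                        if is_patient and frng.uniform() >= crop_p:
                            mu, sig = b.patient_reading_lognorm
                            seg_dur = float(np.clip(frng.lognormal(mu, sig),
                                                    1.0, b.patient_reading_cap))
                        else:
                            seg_dur = b.control_reading_duration
                    else:
                        seg_dur = b.control_reading_duration
                    total = 3 * seg_dur
                    tp_read = _recording_variation(voice, frng)
                    profile = ReadingProfile(
                        f0=tp_read["f0"], jitter=tp_read["jitter"],
                        shimmer=tp_read["shimmer"], hnr=tp_read["hnr"],
                        pause_fraction=min(0.18 + tp_read["pause_add"], 0.5),
                        formant_bw_scale=tp_read["bw_scale"])
                    w = synthesize_reading_proxy(
                        profile, total, spec.sample_rate,
                        seed=_subseed(seed, g, i, task_code, 0, 7))
                    w = _scale_to_level(w, tp_read["level_db"])
                    w, clipped = apply_recording_channel(
                        w, gain, noise_floor,
                        seed=_subseed(seed, g, i, task_code, 0, 11))
                    tp_full = dict(tp_read, gain=gain, noise_floor=noise_floor,
                                   clipped=clipped, severity=severity)
                    full_readings[person.id] = Recording(
                        f"{person.id}_reading_full", person.id, "reading", 0,
                        w, spec.sample_rate, tp_full)
                    third = len(w) // 3
                    for s in range(3):
                        piece = (w[s * third:(s + 1) * third] if s < 2
                                 else w[2 * third:])
                        rid = f"{person.id}_reading_{s + 1}"
                        recordings.append(Recording(
                            rid, person.id, "reading", s + 1, piece,
                            spec.sample_rate, dict(tp_full)))

    for rec in recordings:
        person = next(p for p in participants if p.id == rec.participant_id)
        rows.append({
            "recording_id": rec.recording_id,
            "participant_id": rec.participant_id,
            "group": person.group, "task": rec.task,
            "segment_index": rec.segment_index,
            "age": person.age, "sex": person.sex, "smoking": person.smoking,
            "path": f"{rec.recording_id}.wav",
            "duration": rec.duration,
        })
    manifest = pd.DataFrame(rows)
    return Cohort(spec, participants, recordings, manifest, full_readings)


# ---------------------------------------------------------------------------
# Clinician-rater simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaterProfile:
    """One simulated rater: additive bias and noise on the latent severity."""

    rater_id: int
    bias: float = 0.0
    noise_sd: float = 9.0
    call_threshold: float = 30.0
    category_noise_db: float = 3.0


def default_raters(noise_sd: float = 9.0) -> list[RaterProfile]:
    return [RaterProfile(1, -4.0, noise_sd), RaterProfile(2, 0.0, noise_sd),
            RaterProfile(3, 4.0, noise_sd)]


def noise_sd_for_icc(target_icc: float, latent_sd: float) -> float:
    """Rater noise SD giving an expected single-rater ICC of ``target_icc``.

    From the variance-components identity ICC = s_b^2 / (s_b^2 + s_e^2) for
    between-recording latent variance s_b^2 and rater noise variance s_e^2.
    """
    if not (0 < target_icc < 1):
        raise ValueError("target_icc must be in (0, 1)")
    return latent_sd * np.sqrt(1.0 / target_icc - 1.0)


_SCALES = ("severity", "roughness", "breathiness", "strain", "pitch", "loudness")


def _latent_severity(tp: dict) -> float:
    """Perceptual severity (0-100) driven by the true pathology parameters.

    Clinicians integrate over every audible cue, so the latent reads all
    pathology channels: perturbation, breathiness, resonance damping, and
    phrasing.
    """
    return float(np.clip(
        30.0 * np.log10(max(tp["jitter"], 0.05) / 0.5)
        + 6.0 * (tp["shimmer"] - 3.0)
        + 3.2 * (24.0 - tp["hnr"])
        + 25.0 * (tp.get("bw_scale", 1.0) - 1.0)
        + 300.0 * tp.get("pause_add", 0.0), 0.0, 100.0))


def _scale_latents(tp: dict) -> dict[str, float]:
    sev = _latent_severity(tp)
    return {
        "severity": sev,
        "roughness": float(np.clip(45.0 * np.log10(max(tp["jitter"], 0.05) / 0.4)
                                   + 6.0 * (tp["shimmer"] - 3.0), 0, 100)),
        "breathiness": float(np.clip(4.2 * (24.0 - tp["hnr"])
                                     + 12.0 * (tp.get("bw_scale", 1.0) - 1.0),
                                     0, 100)),
        "strain": float(np.clip(0.6 * sev + 8.0, 0, 100)),
        "pitch": float(np.clip(0.4 * sev + 10.0, 0, 100)),
        "loudness": float(np.clip(-3.0 * (tp["level_db"] + 20.0) + 20.0, 0, 100)),
    }


def generate_rater_table(cohort: Cohort,
                         rater_profiles: list[RaterProfile] | None = None,
                         seed: int | None = None) -> pd.DataFrame:
    """Simulate clinician ratings of the un-split reading passages.

    Numeric 0-100 scales are noisy readings of latent perceptual quantities
    driven by the true pathology parameters; ``recording_loudness`` follows
    the post-channel RMS; ``background_noise`` follows the noise floor; the
    binary call thresholds the noisy severity latent. Inter-rater agreement is
    controlled by the rater noise SD (see :func:`noise_sd_for_icc`).
    """
    raters = default_raters() if rater_profiles is None else rater_profiles
    if len(raters) < 2:
        raise ValueError("at least 2 raters required for reliability analysis")
    if not cohort.full_readings:
        raise ValueError("cohort has no un-split reading recordings to rate")
    seed = cohort.spec.seed if seed is None else seed
    rows = []
    for k, (pid, rec) in enumerate(sorted(cohort.full_readings.items())):
        tp = rec.true_params
        latents = _scale_latents(tp)
        level = rms_db(rec.waveform)
        for r in raters:
            rr = _rng(seed, 90, k, r.rater_id)
            ratings = {s: float(np.clip(latents[s] + r.bias
                                        + rr.normal(0, r.noise_sd), 0, 100))
                       for s in _SCALES}
            call_latent = latents["severity"] + r.bias + rr.normal(0, r.noise_sd)
            noisy_floor = tp["noise_floor"] + rr.normal(0, r.category_noise_db)
            noisy_level = level + rr.normal(0, r.category_noise_db)
            background = ("None" if noisy_floor < -52 else
                          "Some" if noisy_floor < -47 else "High")
            loud = ("low" if noisy_level < -30 else
                    "medium" if noisy_level < -23 else "high")
            rows.append({
                "recording_id": rec.recording_id, "participant_id": pid,
                "rater_id": r.rater_id, "background_noise": background,
                "uvfp_call": "yes" if call_latent > r.call_threshold else "no",
                **ratings, "recording_loudness": loud,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def write_wav(path, waveform: np.ndarray, sample_rate: int = SAMPLE_RATE) -> None:
    """Write a mono 16-bit PCM WAV."""
    pcm = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (pcm * 32767.0).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV")
    if data.dtype == np.int16:
        data = data.astype(float) / 32767.0
    return data.astype(float), int(sr)


def write_cohort(cohort: Cohort, outdir, rater_table: pd.DataFrame | None = None
                 ) -> dict:
    """Write WAVs + manifest.csv + raters.csv + truth.json; returns checksums."""
    from pathlib import Path

    out = Path(outdir)
    (out / "audio").mkdir(parents=True, exist_ok=True)
    checksums = {}
    for rec in cohort.recordings:
        p = out / "audio" / f"{rec.recording_id}.wav"
        write_wav(p, rec.waveform, rec.sample_rate)
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = cohort.manifest.copy()
    manifest["path"] = "audio/" + manifest["recording_id"] + ".wav"
    manifest.to_csv(out / "manifest.csv", index=False)
    truth = {
        "spec": {"n_per_group": cohort.spec.n_per_group,
                 "seed": cohort.spec.seed,
                 "sample_rate": cohort.spec.sample_rate,
                 "pathology": asdict(cohort.spec.pathology),
                 "biases": asdict(cohort.spec.biases)},
        "recordings": {r.recording_id: {k: v for k, v in r.true_params.items()}
                       for r in cohort.recordings},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, default=float))
    if rater_table is not None:
        rater_table.to_csv(out / "raters.csv", index=False)
    return checksums


def participants_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in cohort.participants])
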