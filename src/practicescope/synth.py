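"""Synthetic study generator: MIDI performances, ECG and questionnaires.

Because no raw participant data are deposited for this design, the
generator emulates a cohort of pianists practicing a short octave-leap
task, with a latent-trait structure chosen so that the pipeline's
downstream analyses recover a realistic anxiety-practice-quality pattern:

* pre/post-baseline state anxiety correlates positively with practice
  time (and hence keystroke counts);
* higher state anxiety predicts worse (higher) baseline quality scores
  on the inverted composite scale;
* practice improves quality (negative time effect), with a learning rate
  unrelated to anxiety (null time x anxiety interaction);
* pre- and post-performance anxiety change scores correlate positively,
  and post-performance anxiety change correlates negatively with baseline
  performance scores.

Every stochastic element is driven by a single integer seed; identical
(config, seed) pairs produce byte-identical study trees.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .ecg import EcgRecording, write_ecg_csv
from .midi_scoring import NoteEvent, PerformanceRecording
from .score import TargetScore, make_target_score, save_score
from .smf import SmfNote, write_smf

TRAIT_NAMES = (
    "trait_anxiety",
    "state_anxiety_base",
    "baseline_skill",
    "learning_rate",
    "cardiac_tone",
    "anxiety_drift",
)

# Empirical gain of the retained composite per unit of latent badness:
# converts effects configured on the score scale to the latent z-scale.
LATENT_TO_SCORE = 0.9

# Inter-repetition pause distribution (s): truncated normal
PAUSE_MEAN, PAUSE_SD, PAUSE_MIN = 2.21, 1.13, 0.5


@dataclass(frozen=True)
class LatentTraits:
    """Per-participant ground truth, all on z-scales except noted."""

    trait_anxiety: float
    state_anxiety_base: float
    baseline_skill: float
    learning_rate: float  # z-score; actual rate derived from config
    cardiac_tone: float  # z-score; bpm offset via ecg model
    anxiety_drift: float  # shared factor of anxiety change over the session


def default_trait_correlations() -> np.ndarray:
    c = np.eye(len(TRAIT_NAMES))
    idx = {n: i for i, n in enumerate(TRAIT_NAMES)}

    def set_r(a: str, b: str, r: float) -> None:
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r

    set_r("trait_anxiety", "state_anxiety_base", 0.5)
    set_r("trait_anxiety", "baseline_skill", -0.25)
    # performers whose anxiety rises over the session learn the least
    set_r("learning_rate", "anxiety_drift", -0.8)
    return c


@dataclass(frozen=True)
class ErrorRateModel:
    """Maps latent badness z to the four quality-parameter noise levels.

    Rates respond *linearly* to badness (with a small positive floor), so
    the composite score is approximately linear in the latent trajectory
    and learning is homogeneous on the score scale; the floor produces the
    natural ceiling effect for strong players who cannot commit negative
    errors.
    """

    wrong_rate: float = 3.0  # expected wrong notes per assessment at z=0
    missed_rate: float = 2.0
    rate_gain: float = 0.6  # relative rate change per badness SD
    rate_floor: float = 0.03  # fraction of the z=0 rate
    ioi_jitter_sd: float = 0.020  # s, at z=0
    # 0: the metronome clamps timing variability for every player, so the
    # rhythmic-accuracy indicator carries no between-person signal
    # (measurement at ceiling) and fails composite retention
    ioi_jitter_gain: float = 0.0
    velocity_sd: float = 6.0  # MIDI velocity units at z=0
    velocity_gain: float = 0.30
    velocity_floor: float = 0.2  # fraction of the z=0 spread
    base_velocity: float = 70.0


@dataclass(frozen=True)
class PracticeTimeModel:
    intercept_min: float = 26.0
    slope_min_per_sd: float = 5.0  # minutes per SD of state anxiety
    noise_sd_min: float = 10.0
    min_minutes: float = 2.0
    mean_ioi_s: float = 0.35
    ioi_between_sd_s: float = 0.05  # between-participant keystroke-rate spread
    off_target_fraction: float = 0.12
    off_target_log_sd: float = 0.5  # multiplicative between-participant spread


@dataclass(frozen=True)
class EcgModel:
    base_hr: float = 72.0  # bpm
    anxiety_hr_gain: float = 4.0  # bpm per SD of state anxiety
    cardiac_tone_sd: float = 6.0  # bpm per SD of cardiac tone
    rr_noise_sd: float = 0.030  # s
    rr_noise_anxiety_gain: float = -0.10  # log-SD units per anxiety SD
    drift_sd: float = 0.5  # bpm/min, per-participant HR drift
    duration_s: float = 120.0
    fs: float = 1000.0
    snr_db: float = 20.0


@dataclass(frozen=True)
class SynthConfig:
    n_participants: int = 30
    trait_correlations: np.ndarray = field(default_factory=default_trait_correlations)
    effect_time: float = -0.05  # quality-score units per practice minute
    effect_anxiety: float = 0.4  # quality-score units per anxiety SD
    learning_rate_sd: float = 0.04  # score units/min, between-performer spread
    practice_time_model: PracticeTimeModel = field(default_factory=PracticeTimeModel)
    error_rate_model: ErrorRateModel = field(default_factory=ErrorRateModel)
    ecg_model: EcgModel = field(default_factory=EcgModel)
    vasa_mean: float = 4.0
    vasa_sd: float = 2.0
    include_ecg: bool = True
    seed: int = 0

    def validate(self) -> None:
        c = np.asarray(self.trait_correlations, float)
        if c.shape != (len(TRAIT_NAMES),) * 2:
            raise ValueError("trait_correlations has wrong shape")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("trait_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("trait_correlations must be positive semidefinite")
        erm, ptm = self.error_rate_model, self.practice_time_model
        if min(erm.wrong_rate, erm.missed_rate, erm.ioi_jitter_sd, erm.velocity_sd) < 0:
            raise ValueError("error rates and noise SDs must be >= 0")
        if ptm.noise_sd_min < 0 or self.ecg_model.rr_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class ParticipantRecord:
    participant_id: str
    traits: LatentTraits
    baseline: PerformanceRecording
    acquisition: PerformanceRecording
    practice: PerformanceRecording
    questionnaire: dict
    practice_minutes: float
    ecg: EcgRecording | None = None
    ecg_truth_peaks: np.ndarray | None = None


@dataclass
class StudyDataset:
    score: TargetScore
    participants: list[ParticipantRecord]
    questionnaires: pd.DataFrame
    ground_truth: dict
    config: SynthConfig


def sample_participants(config: SynthConfig, rng: np.random.Generator | None = None) -> list[LatentTraits]:
    """Draw the latent trait vectors from the configured MVN."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    c = np.asarray(config.trait_correlations, float)
    draws = rng.multivariate_normal(np.zeros(len(TRAIT_NAMES)), c,
                                    size=config.n_participants, method="cholesky")
    return [LatentTraits(*map(float, row)) for row in draws]


def latent_badness(traits: LatentTraits, config: SynthConfig) -> float:
    """Baseline performance 'badness' z-score (high = poor playing).

    ``effect_anxiety`` doubles as the latent anxiety-badness correlation:
    on the composite scale the anxiety coefficient approximately equals
    that correlation because the standardized score has near-unit SD.
    """
    ea = min(max(config.effect_anxiety, 0.0), 0.95)
    return ea * traits.state_anxiety_base - np.sqrt(1 - ea**2) * traits.baseline_skill


def badness_at(traits: LatentTraits, practice_minutes: float, config: SynthConfig) -> float:
    # higher learning_rate trait -> steeper decline on the inverted scale;
    # capped at zero: practice does not make playing worse
    rate = min(config.effect_time - config.learning_rate_sd * traits.learning_rate, 0.0)
    return latent_badness(traits, config) + rate / LATENT_TO_SCORE * practice_minutes


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    while np.any(out < lo):  # resample below-floor draws
        bad = out < lo
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return out


def _wrong_pitch(rng: np.random.Generator, target_pitch: int) -> int:
    # one semitone or a tritone off target, equal probability, direction random
    step = 1 if rng.random() < 0.5 else 6
    sign = 1 if rng.random() < 0.5 else -1
    p = target_pitch + sign * step
    return int(min(max(p, 21), 108))


def render_performance(
    traits: LatentTraits,
    score: TargetScore,
    phase: Literal["baseline", "acquisition"],
    practice_minutes: float,
    seed: int | np.random.Generator,
    config: SynthConfig | None = None,
) -> PerformanceRecording:
    """Render one assessment: n repetitions with pauses, noise and errors.

    Wrong-note insertions and missed-note deletions are Poisson with rates
    decreasing in skill plus accumulated practice; onset jitter and
    velocity spread are Gaussian at levels set by the error-rate model.
    """
    if practice_minutes < 0:
        raise ValueError("practice_minutes must be >= 0")
    config = config or SynthConfig()
    erm = config.error_rate_model
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = badness_at(traits, practice_minutes, config)
    level = max(1.0 + erm.rate_gain * b, erm.rate_floor)
    wrong_rate = erm.wrong_rate * level / score.n_repetitions
    missed_rate = erm.missed_rate * level / score.n_repetitions
    jitter = erm.ioi_jitter_sd * np.exp(erm.ioi_jitter_gain * b)
    vel_sd = erm.velocity_sd * max(1.0 + erm.velocity_gain * b, erm.velocity_floor)

    nominal = np.asarray(score.nominal_onsets_s)
    events: list[NoteEvent] = []
    t_rep = 1.0  # lead-in before the first repetition
    for _ in range(score.n_repetitions):
        n_miss = min(int(rng.poisson(missed_rate)), max(len(nominal) - 1, 0))
        missed_idx = set(rng.choice(len(nominal), size=n_miss, replace=False)) if n_miss else set()
        onsets = t_rep + nominal + rng.normal(0.0, jitter, size=len(nominal))
        for i, t in enumerate(onsets):
            if i in missed_idx:
                continue
            vel = int(np.clip(round(rng.normal(erm.base_velocity, vel_sd)), 1, 127))
            dur = score.notes[i].duration_beats * score.beat_s * 0.9
            events.append(NoteEvent(score.notes[i].pitch, float(t), float(t + dur), vel))
        for _ in range(rng.poisson(wrong_rate)):
            ti = int(rng.integers(len(nominal)))
            t = float(onsets[ti] + rng.uniform(-0.08, 0.08))
            vel = int(np.clip(round(rng.normal(erm.base_velocity, vel_sd)), 1, 127))
            events.append(NoteEvent(_wrong_pitch(rng, score.notes[ti].pitch), t, t + 0.12, vel))
        pause = float(_truncnorm(rng, PAUSE_MEAN, PAUSE_SD, PAUSE_MIN, 1)[0])
        t_rep += score.repetition_span_s + pause
    events.sort(key=lambda e: (e.onset, e.pitch))
    return PerformanceRecording(tuple(events), phase=phase)


def render_practice_session(
    traits: LatentTraits,
    score: TargetScore,
    seed: int | np.random.Generator,
    config: SynthConfig | None = None,
    anxiety_driver: float | None = None,
) -> tuple[PerformanceRecording, float]:
    """Render a free practice session; returns (recording, duration_min).

    Session duration is max(floor, intercept + slope * anxiety + noise)
    minutes, where the anxiety driver defaults to pre-baseline state
    anxiety (the study generator passes the standardized mean of the two
    pre-practice anxiety ratings, both of which precede the session);
    keystrokes stream at the model's mean IOI, mostly on the task's pitch
    set with a configurable off-target fraction.
    """
    config = config or SynthConfig()
    ptm = config.practice_time_model
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if anxiety_driver is None:
        anxiety_driver = traits.state_anxiety_base
    duration_min = max(
        ptm.min_minutes,
        ptm.intercept_min
        + ptm.slope_min_per_sd * anxiety_driver
        + rng.normal(0.0, ptm.noise_sd_min),
    )
    duration_s = duration_min * 60.0
    ioi = max(0.15, rng.normal(ptm.mean_ioi_s, ptm.ioi_between_sd_s))
    n_events = max(int(round(duration_s / ioi)), 2)
    onsets = np.linspace(0.0, duration_s, n_events)
    onsets[1:-1] += rng.normal(0.0, 0.05, size=n_events - 2)
    onsets.sort()
    pitches = np.asarray(sorted(score.pitch_set))
    pick = rng.integers(len(pitches), size=n_events)
    pitch_arr = pitches[pick]
    off_frac = float(np.clip(
        ptm.off_target_fraction * np.exp(rng.normal(0.0, ptm.off_target_log_sd)),
        0.0, 0.5))
    off = rng.random(n_events) < off_frac
    if off.any():
        pitch_arr = pitch_arr.copy()
        pitch_arr[off] = [_wrong_pitch(rng, int(p)) for p in pitch_arr[off]]
    vels = np.clip(np.round(rng.normal(config.error_rate_model.base_velocity, 8.0, n_events)), 1, 127)
    events = tuple(
        NoteEvent(int(p), float(t), float(t + 0.2), int(v))
        for p, t, v in zip(pitch_arr, onsets, vels)
    )
    return PerformanceRecording(events, phase="practice"), float(duration_min)


def synthesize_ecg(
    traits: LatentTraits,
    duration: float,
    fs: float,
    seed: int | np.random.Generator,
    config: SynthConfig | None = None,
    drift_bpm_per_min: float | None = None,
    rr_noise_sd: float | None = None,
    snr_db: float | None = None,
    base_hr: float | None = None,
) -> tuple[EcgRecording, np.ndarray]:
    """Synthesize a single-lead ECG; returns (recording, true peak times).

    R waves are Gaussian templates (1 mV, sigma 10 ms) placed at RR
    intervals 60/(HR + drift*t) plus Gaussian RR noise, with additive
    broadband noise at the configured SNR.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs < 250:
        raise ValueError("sampling rate must be >= 250 Hz")
    config = config or SynthConfig()
    em = config.ecg_model
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if base_hr is None:
        base_hr = (
            em.base_hr
            + em.anxiety_hr_gain * traits.state_anxiety_base
            + em.cardiac_tone_sd * traits.cardiac_tone
        )
    if drift_bpm_per_min is None:
        drift_bpm_per_min = float(em.drift_sd * traits.cardiac_tone)
    if rr_noise_sd is None:
        rr_noise_sd = em.rr_noise_sd * float(
            np.exp(em.rr_noise_anxiety_gain * traits.state_anxiety_base)
        )
    snr_db = em.snr_db if snr_db is None else snr_db

    peaks = []
    t = 0.3
    while t < duration - 0.3:
        peaks.append(t)
        hr_t = max(base_hr + drift_bpm_per_min * t / 60.0, 25.0)
        rr = 60.0 / hr_t
        if rr_noise_sd > 0:
            rr = max(rr + rng.normal(0.0, rr_noise_sd), 0.30)
        t += rr
    peak_times = np.asarray(peaks)

    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    x = np.zeros(n)
    sigma = 0.010  # s
    half = int(round(4 * sigma * fs))
    for p in peak_times:
        c = int(round(p * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        x[lo:hi] += np.exp(-0.5 * ((tt[lo:hi] - p) / sigma) ** 2)
    if np.isfinite(snr_db):
        noise_sd = float(np.sqrt(np.var(x) / 10 ** (snr_db / 10.0)))
        x = x + rng.normal(0.0, noise_sd, size=n)
    return EcgRecording(samples=x, fs=fs), peak_times


def _vasa(rng: np.random.Generator, latent: float, config: SynthConfig) -> int:
    v = config.vasa_mean + config.vasa_sd * latent
    return int(np.clip(round(v), 0, 10))


def _stai_sum(rng: np.random.Generator, latent: float, loading: float = 0.55) -> int:
    # 20 four-point items sharing one latent factor
    item_latent = loading * latent + np.sqrt(1 - loading**2) * rng.normal(size=20)
    items = np.clip(np.round(2.5 + 0.9 * item_latent), 1, 4)
    return int(items.sum())


def _anxiety_timecourse(
    traits: LatentTraits, badness: float, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Latent state anxiety at the four VASA timepoints.

    v2 mixes baseline anxiety with baseline badness-driven arousal; the
    changes share the anxiety-drift factor, and the post-performance
    change additionally decreases with baseline badness (poor starters
    relax the most once they improve).
    """
    a = traits.state_anxiety_base
    drift = traits.anxiety_drift
    v1 = a
    v2 = 0.4 * a + 0.45 * badness + 0.702 * rng.normal()
    d_pre = -0.15 + 0.75 * drift + 0.661 * rng.normal()
    d_post = -0.25 + 0.75 * drift - 0.6 * badness + 0.278 * rng.normal()
    return v1, v2, v1 + d_pre, v2 + d_post


def generate_study(
    config: SynthConfig | None = None,
    out_dir: str | Path | None = None,
    score: TargetScore | None = None,
) -> StudyDataset:
    """Generate a complete synthetic study; optionally write it to disk.

    The on-disk layout is ``study/<pid>/{baseline.mid, practice.mid,
    acquisition.mid, ecg.csv}`` plus ``questionnaires.csv``,
    ``target_score.json`` and ``manifest.json`` (seed, config, per-
    participant ground truth).
    """
    config = config or SynthConfig()
    config.validate()
    score = score or make_target_score()
    ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    traits_list = sample_participants(config, master)
    child_seeds = ss.spawn(config.n_participants)

    participants: list[ParticipantRecord] = []
    rows = []
    truth = {}
    for i, traits in enumerate(traits_list):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(child_seeds[i])
        v1, v2, v3, v4 = _anxiety_timecourse(traits, latent_badness(traits, config), rng)
        # both pre-practice anxiety ratings drive how long people practice;
        # their mean is standardized by its model-implied SD
        driver = (v1 + v2) / 1.78
        practice, practice_min = render_practice_session(
            traits, score, rng, config, anxiety_driver=driver)
        baseline = render_performance(traits, score, "baseline", 0.0, rng, config)
        acquisition = render_performance(traits, score, "acquisition", practice_min, rng, config)
        ecg = truth_peaks = None
        if config.include_ecg:
            ecg, truth_peaks = synthesize_ecg(
                traits, config.ecg_model.duration_s, config.ecg_model.fs, rng, config
            )
        q = dict(
            id=pid,
            age=float(np.clip(round(rng.normal(24.13, 3.92), 1), 18, 45)),
            gender="female" if rng.random() < 0.6 else "male",
            lifetime_practice_h=int(max(rng.normal(17723, 10273), 1000)),
            stai_t=_stai_sum(rng, traits.trait_anxiety),
            stai_s=_stai_sum(rng, 0.5 * traits.trait_anxiety + 0.6 * traits.state_anxiety_base),
            vasa1=_vasa(rng, v1, config),
            vasa2=_vasa(rng, v2, config),
            vasa3=_vasa(rng, v3, config),
            vasa4=_vasa(rng, v4, config),
        )
        rows.append(q)
        truth[pid] = dict(
            traits=dataclasses.asdict(traits),
            practice_minutes=practice_min,
            badness_baseline=latent_badness(traits, config),
            badness_acquisition=badness_at(traits, practice_min, config),
            vasa_latent=[v1, v2, v3, v4],
        )
        participants.append(ParticipantRecord(
            participant_id=pid, traits=traits, baseline=baseline,
            acquisition=acquisition, practice=practice, questionnaire=q,
            practice_minutes=practice_min, ecg=ecg, ecg_truth_peaks=truth_peaks,
        ))

    questionnaires = pd.DataFrame(rows)
    dataset = StudyDataset(score, participants, questionnaires,
                           dict(seed=config.seed, participants=truth), config)
    if out_dir is not None:
        _write_study(dataset, Path(out_dir))
    return dataset


def _rec_to_smf_notes(rec: PerformanceRecording) -> list[SmfNote]:
    return [SmfNote(e.pitch, e.onset, e.offset, max(e.velocity, 1)) for e in rec.events]


def _config_to_jsonable(config: SynthConfig) -> dict:
    d = dataclasses.asdict(config)
    d["trait_correlations"] = np.asarray(config.trait_correlations).tolist()
    return d


def _write_study(dataset: StudyDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tempo = dataset.score.tempo_bpm
    for p in dataset.participants:
        pdir = out_dir / p.participant_id
        pdir.mkdir(exist_ok=True)
        write_smf(_rec_to_smf_notes(p.baseline), pdir / "baseline.mid", tempo)
        write_smf(_rec_to_smf_notes(p.acquisition), pdir / "acquisition.mid", tempo)
        write_smf(_rec_to_smf_notes(p.practice), pdir / "practice.mid", tempo)
        if p.ecg is not None:
            write_ecg_csv(p.ecg, pdir / "ecg.csv")
    dataset.questionnaires.to_csv(out_dir / "questionnaires.csv", index=False)
    save_score(dataset.score, out_dir / "target_score.json")
    manifest = dict(
        seed=dataset.config.seed,
        config=_config_to_jsonable(dataset.config),
        ground_truth=dataset.ground_truth,
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
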