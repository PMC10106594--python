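"""Synthetic study generator: determinism, trait structure, noise models."""

import json

import numpy as np
import pytest

from practicescope.midi_scoring import assess_performance, practice_descriptors
from practicescope.score import make_target_score
from practicescope.synth import (
    ErrorRateModel,
    LatentTraits,
    PracticeTimeModel,
    SynthConfig,
    TRAIT_NAMES,
    default_trait_correlations,
    generate_study,
    render_performance,
    render_practice_session,
    sample_participants,
    synthesize_ecg,
)

TRAITS0 = LatentTraits(0, 0, 0, 0, 0, 0)


def _traits_matrix(traits_list):
    return np.array([[getattr(t, n) for n in TRAIT_NAMES] for t in traits_list])


# ---------------------------------------------------------------------------
# target score


def test_default_score_ioi_and_pitch_set():
    sc = make_target_score(90, 5)
    iois = np.diff(sc.nominal_onsets_s)
    assert iois == pytest.approx(np.full(len(iois), 60 / 90 / 2))
    assert sc.pitch_set == {60, 72}  # two octave-separated pitch classes
    assert sc.n_repetitions == 5

    quarter = make_target_score(60, 1, note_value_beats=1.0)
    assert np.diff(quarter.nominal_onsets_s) == pytest.approx(
        np.full(len(quarter.notes) - 1, 1.0)
    )


def test_invalid_tempo_rejected():
    with pytest.raises(ValueError):
        make_target_score(tempo_bpm=0)
    with pytest.raises(ValueError):
        make_target_score(n_repetitions=0)


# ---------------------------------------------------------------------------
# participant sampling


def test_identity_correlation_gives_uncorrelated_traits():
    cfg = SynthConfig(n_participants=100_000, trait_correlations=np.eye(6), seed=0)
    m = _traits_matrix(sample_participants(cfg))
    corr = np.corrcoef(m, rowvar=False)
    off = corr[~np.eye(6, dtype=bool)]
    assert np.abs(off).max() < 0.02


def test_configured_correlation_recovered():
    c = np.eye(6)
    i, j = TRAIT_NAMES.index("state_anxiety_base"), TRAIT_NAMES.index("baseline_skill")
    c[i, j] = c[j, i] = -0.5
    cfg = SynthConfig(n_participants=10_000, trait_correlations=c, seed=1)
    m = _traits_matrix(sample_participants(cfg))
    r = np.corrcoef(m[:, i], m[:, j])[0, 1]
    assert r == pytest.approx(-0.5, abs=0.03)


def test_same_seed_identical_draws():
    cfg = SynthConfig(n_participants=50, seed=42)
    assert sample_participants(cfg) == sample_participants(cfg)


def test_non_psd_matrix_rejected():
    c = np.eye(6)
    c[0, 1] = c[1, 0] = 0.9
    c[1, 2] = c[2, 1] = 0.9
    c[0, 2] = c[2, 0] = -0.9  # violates PSD
    with pytest.raises(ValueError, match="positive semidefinite"):
        SynthConfig(trait_correlations=c).validate()


# ---------------------------------------------------------------------------
# performance rendering


def _noiseless_config():
    erm = ErrorRateModel(wrong_rate=0.0, missed_rate=0.0, ioi_jitter_sd=0.0,
                         velocity_sd=0.0)
    return SynthConfig(error_rate_model=erm)


def test_noiseless_rendition_scores_clean(score):
    cfg = _noiseless_config()
    rec = render_performance(TRAITS0, score, "baseline", 0.0, seed=0, config=cfg)
    res = assess_performance(rec, score)
    assert (res.wrong_notes, res.missed_notes) == (0, 0)
    assert res.rhythmic_accuracy == pytest.approx(0.0, abs=1e-9)
    assert res.loudness_homogeneity == pytest.approx(0.0, abs=1e-9)


def test_wrong_note_poisson_mean(score):
    """Scored wrong notes recover the configured insertion rate."""
    erm = ErrorRateModel(wrong_rate=2.0, missed_rate=0.0, rate_gain=0.0,
                         ioi_jitter_sd=0.0, velocity_sd=0.0)
    cfg = SynthConfig(error_rate_model=erm)
    rng = np.random.default_rng(3)
    total = 0
    n_rend = 800
    for _ in range(n_rend):
        rec = render_performance(TRAITS0, score, "baseline", 0.0, rng, cfg)
        total += assess_performance(rec, score).wrong_notes
    assert total / n_rend == pytest.approx(2.0, abs=0.15)


def test_practice_reduces_expected_errors(score):
    traits = LatentTraits(0, 0, 0, 0, 0, 0)
    cfg = SynthConfig()
    rng = np.random.default_rng(4)
    err0 = err1 = 0
    for _ in range(200):
        r0 = assess_performance(
            render_performance(traits, score, "baseline", 0.0, rng, cfg), score)
        r1 = assess_performance(
            render_performance(traits, score, "acquisition", 30.0, rng, cfg), score)
        err0 += r0.wrong_notes + r0.missed_notes
        err1 += r1.wrong_notes + r1.missed_notes
    assert err1 < err0


def test_pause_distribution_moments(score):
    """Inter-repetition pauses follow the truncated normal (2.21, 1.13, >=0.5)."""
    from scipy import stats

    from practicescope.synth import PAUSE_MEAN, PAUSE_MIN, PAUSE_SD, _truncnorm

    rng = np.random.default_rng(5)
    draws = _truncnorm(rng, PAUSE_MEAN, PAUSE_SD, PAUSE_MIN, 20_000)
    a = (PAUSE_MIN - PAUSE_MEAN) / PAUSE_SD
    ref = stats.truncnorm(a, np.inf, loc=PAUSE_MEAN, scale=PAUSE_SD)
    assert draws.min() >= PAUSE_MIN
    assert draws.mean() == pytest.approx(ref.mean(), abs=0.03)
    assert draws.std(ddof=1) == pytest.approx(ref.std(), abs=0.03)

    # rendition-level: observed pauses sit in the plausible band
    cfg = _noiseless_config()
    last_note_s = score.notes[-1].duration_beats * score.beat_s
    pauses = []
    for _ in range(100):
        rec = render_performance(TRAITS0, score, "baseline", 0.0, rng, cfg)
        gaps = np.diff([e.onset for e in rec.events])
        pauses.extend(g - last_note_s for g in gaps[gaps > 1.0])
    pauses = np.array(pauses)
    assert pauses.min() >= PAUSE_MIN - 1e-9
    assert 2.0 < pauses.mean() < 2.7


# ---------------------------------------------------------------------------
# practice sessions


def test_deterministic_practice_duration(score):
    ptm = PracticeTimeModel(intercept_min=10.0, slope_min_per_sd=0.0, noise_sd_min=0.0)
    cfg = SynthConfig(practice_time_model=ptm)
    rec, minutes = render_practice_session(TRAITS0, score, seed=0, config=cfg)
    assert minutes == pytest.approx(10.0)
    d = practice_descriptors(rec, score)
    assert d.practice_time == pytest.approx(10.0, abs=0.01)


def test_anxiety_lengthens_practice(score):
    cfg = SynthConfig()
    rng = np.random.default_rng(6)
    anx, mins = [], []
    for _ in range(2000):
        a = rng.normal()
        traits = LatentTraits(0, a, 0, 0, 0, 0)
        _, m = render_practice_session(traits, score, rng, cfg)
        anx.append(a)
        mins.append(m)
    assert np.corrcoef(anx, mins)[0, 1] > 0.3


def test_zero_off_target_fraction(score):
    ptm = PracticeTimeModel(off_target_fraction=0.0, intercept_min=5.0,
                            slope_min_per_sd=0.0, noise_sd_min=0.0)
    cfg = SynthConfig(practice_time_model=ptm)
    rec, _ = render_practice_session(TRAITS0, score, seed=1, config=cfg)
    d = practice_descriptors(rec, score)
    assert d.keystrokes_on_target == d.total_keystrokes


# ---------------------------------------------------------------------------
# study generation


def test_study_tree_layout(tmp_path):
    cfg = SynthConfig(n_participants=3, seed=9)
    generate_study(cfg, out_dir=tmp_path / "study")
    root = tmp_path / "study"
    assert (root / "questionnaires.csv").exists()
    assert (root / "manifest.json").exists()
    assert (root / "target_score.json").exists()
    for pid in ("P001", "P002", "P003"):
        for f in ("baseline.mid", "acquisition.mid", "practice.mid", "ecg.csv"):
            assert (root / pid / f).exists()
    manifest = json.loads((root / "manifest.json").read_text())
    assert manifest["seed"] == 9
    assert len(manifest["ground_truth"]["participants"]) == 3


def test_questionnaire_ranges():
    cfg = SynthConfig(n_participants=60, seed=10, include_ecg=False)
    ds = generate_study(cfg)
    q = ds.questionnaires
    for col in ("vasa1", "vasa2", "vasa3", "vasa4"):
        assert q[col].between(0, 10).all()
        assert (q[col] == q[col].astype(int)).all()
    for col in ("stai_t", "stai_s"):
        assert q[col].between(20, 80).all()


def test_generation_byte_identical_under_seed(tmp_path):
    cfg = SynthConfig(n_participants=2, seed=11)
    generate_study(cfg, out_dir=tmp_path / "a")
    generate_study(cfg, out_dir=tmp_path / "b")
    for rel in ("questionnaires.csv", "P001/baseline.mid", "P001/practice.mid",
                "P001/ecg.csv", "P002/acquisition.mid"):
        assert (tmp_path / "a" / rel).read_bytes() == (tmp_path / "b" / rel).read_bytes()


def test_null_config_kills_anxiety_practice_link():
    """With anxiety decoupled from practice time, the correlation vanishes."""
    ptm = PracticeTimeModel(slope_min_per_sd=0.0)
    cfg = SynthConfig(n_participants=400, seed=12, include_ecg=False,
                      practice_time_model=ptm)
    ds = generate_study(cfg)
    q = ds.questionnaires
    minutes = [p.practice_minutes for p in ds.participants]
    r = np.corrcoef(q["vasa1"], minutes)[0, 1]
    assert abs(r) < 0.1


# ---------------------------------------------------------------------------
# ECG synthesis


def test_clean_ecg_truth_peaks_exactly_spaced():
    _, truth = synthesize_ecg(TRAITS0, 30, 1000, seed=0, snr_db=np.inf,
                              base_hr=60, drift_bpm_per_min=0, rr_noise_sd=0.0)
    assert np.diff(truth) == pytest.approx(np.ones(len(truth) - 1), abs=1e-12)


def test_ecg_duration_and_rate_validation():
    with pytest.raises(ValueError):
        synthesize_ecg(TRAITS0, 0.0, 1000, seed=0)
    with pytest.raises(ValueError):
        synthesize_ecg(TRAITS0, 10.0, 100, seed=0)
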