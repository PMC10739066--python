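"""Generator properties: point process, behavior mixture, arousal, determinism."""

import numpy as np
import pytest
from scipy import stats

from aggrisk.features import FeatureConfig, extract_window
from aggrisk.synthetic import (
    ArousalConfig,
    Episode,
    EpisodeProcessConfig,
    corpus_preset,
    corpus_process_preset,
    generate_sessions,
    generate_structure,
    scaled_preset,
    simulate_episode_times,
    synthesize_signals,
)


def test_explosive_process_rejected():
    with pytest.raises(ValueError, match="explosive"):
        EpisodeProcessConfig(excitation_jump=0.02, excitation_decay=0.01)


def test_zero_rate_yields_no_episodes():
    cfg = EpisodeProcessConfig(base_rate_per_h=0.0, excitation_jump=0.0)
    assert simulate_episode_times(cfg, 3600.0, np.random.default_rng(0)) == []


def test_poisson_limit_gap_distribution():
    """With no self-excitation, inter-onset gaps are exponential."""
    cfg = EpisodeProcessConfig(
        base_rate_per_h=60.0, excitation_jump=0.0,
        duration_medians_s=(0.2, 0.2, 0.2), duration_sigma=0.1,
    )
    rng = np.random.default_rng(1)
    onsets = [e.onset_s for e in simulate_episode_times(cfg, 150_000.0, rng)]
    gaps = np.diff(onsets)
    assert len(gaps) > 2000
    p = stats.kstest(gaps, "expon", args=(0, 3600.0 / 60.0)).pvalue
    assert p > 0.01


def test_behavior_mixture_ratio():
    """SIB:ED frequency ratio matches the configured corpus mixture (~1.93)."""
    cfg = EpisodeProcessConfig(
        base_rate_per_h=120.0, excitation_jump=0.0,
        duration_medians_s=(0.2, 0.2, 0.2), duration_sigma=0.1,
    )
    rng = np.random.default_rng(2)
    eps = simulate_episode_times(cfg, 300_000.0, rng)
    assert len(eps) > 9000
    n = {b: sum(e.behavior == b for e in eps) for b in ("SIB", "ED", "ATO")}
    assert n["SIB"] / n["ED"] == pytest.approx(0.598 / 0.310, abs=0.1)


def test_duration_medians_recovered():
    cfg = EpisodeProcessConfig(base_rate_per_h=120.0, excitation_jump=0.0)
    rng = np.random.default_rng(3)
    eps = simulate_episode_times(cfg, 400_000.0, rng)
    for b, med in zip(("SIB", "ED", "ATO"), (1.97, 10.09, 2.31)):
        durs = [e.duration_s for e in eps if e.behavior == b]
        assert len(durs) > 500
        assert np.median(durs) == pytest.approx(med, rel=0.15)


def test_self_excitation_makes_recency_informative():
    """Time since the previous episode is stochastically smaller just before
    an onset than at background instants when the process self-excites."""
    cfg = EpisodeProcessConfig(base_rate_per_h=20.0)
    rng = np.random.default_rng(4)
    pre, background = [], []
    for _ in range(40):
        eps = simulate_episode_times(cfg, 7200.0, rng)
        onsets = np.array([e.onset_s for e in eps])
        if onsets.size < 3:
            continue
        for o in onsets[1:]:
            prev = onsets[onsets < o]
            pre.append(o - prev.max())
        for t in rng.uniform(0, 7200.0, size=onsets.size):
            prev = onsets[onsets < t]
            if prev.size:
                background.append(t - prev.max())
    assert len(pre) > 200 and len(background) > 200
    p = stats.mannwhitneyu(pre, background, alternative="less").pvalue
    assert p < 1e-3


def test_same_behavior_overlaps_merged():
    eps = [
        Episode(10.0, "SIB", 5.0, "low"),
        Episode(12.0, "SIB", 10.0, "high"),
        Episode(12.0, "ED", 1.0, "low"),
    ]
    from aggrisk.synthetic import _merge_same_behavior

    merged = _merge_same_behavior(eps)
    sib = [e for e in merged if e.behavior == "SIB"]
    assert len(sib) == 1 and sib[0].offset_s == 22.0 and sib[0].intensity == "high"
    assert len(merged) == 2


def test_hr_effect_construction_oracle():
    """A window fully covering the ramp end sees ~the configured HR rise."""
    rng = np.random.default_rng(5)
    base = ArousalConfig.null(hr_wander_sd_bpm=0.5, hrv_sd_bpm=1.0)
    eff = ArousalConfig(hr_effect_bpm=20.0, hr_wander_sd_bpm=0.5, hrv_sd_bpm=1.0)
    cfg = FeatureConfig(tau_p=60.0)
    diffs = []
    for _ in range(5):
        eps = [Episode(480.0, "SIB", 5.0, "mid")]
        rec0 = synthesize_signals(eps, base, 600.0, np.random.default_rng(rng.integers(2**31)))
        rec1 = synthesize_signals(eps, eff, 600.0, np.random.default_rng(rng.integers(2**31)))
        h0 = extract_window(rec0, 480.0, cfg).values[4]
        h1 = extract_window(rec1, 480.0, cfg).values[4]
        diffs.append(h1 - h0)
    # window (420, 480] sits in the last third of the 180-s ramp: mean ramp ~0.83
    assert np.mean(diffs) == pytest.approx(20.0 * 0.83, abs=4.0)


def test_intensity_classes_order_movement():
    rng = np.random.default_rng(6)
    ar = ArousalConfig.null()
    mags = {}
    for intensity in ("low", "mid", "high"):
        eps = [Episode(300.0, "ED", 30.0, intensity)]
        rec = synthesize_signals(eps, ar, 600.0, np.random.default_rng(rng.integers(2**31)))
        seg = rec.acc.samples[int(300 * 32) : int(330 * 32)]
        mags[intensity] = np.mean(np.abs(np.linalg.norm(seg, axis=1) - 1.0))
    assert mags["low"] < mags["mid"] < mags["high"]


def test_generation_deterministic_under_seed():
    a = generate_sessions(scaled_preset(7, 2, 2, 600.0))
    b = generate_sessions(scaled_preset(7, 2, 2, 600.0))
    assert a.episode_truth().equals(b.episode_truth())
    for sa, sb in zip(a.sessions_list, b.sessions_list):
        for name in ("eda", "bvp", "acc"):
            assert np.array_equal(
                sa.recording.channels[name].samples,
                sb.recording.channels[name].samples,
            )


def test_minimal_dataset_valid():
    ds = generate_sessions(scaled_preset(0, 1, 1, 600.0))
    assert len(ds.sessions_list) == 1
    rec = ds.sessions_list[0].recording
    assert rec.duration_s == pytest.approx(600.0)


def test_ramp_longer_than_session_rejected():
    with pytest.raises(ValueError, match="ramp"):
        synthesize_signals([], ArousalConfig(), 100.0, np.random.default_rng(0))


def test_corpus_structure_matches_reference_medians():
    """Corpus-scale structure lands inside the emulated study's IQRs."""
    anns, sess = generate_structure(corpus_preset(0), corpus_process_preset())
    n_sessions = sess.groupby("participant").size()
    assert 1 <= np.median(n_sessions) <= 7
    assert 1.26 <= np.median(sess["duration_s"]) / 3600.0 <= 10.96
    parts = sess["participant"].unique()
    iqrs = {"SIB": (0, 23, 0.72, 4.97), "ED": (0, 27, 4.47, 24.54), "ATO": (0, 8, 1.07, 4.83)}
    for b, (clo, chi, dlo, dhi) in iqrs.items():
        eps = [a for a in anns if a.behavior == b]
        cnt = [sum(1 for a in eps if a.participant_id == p) for p in parts]
        assert clo <= np.median(cnt) <= chi
        assert dlo <= np.median([a.duration_s for a in eps]) <= dhi
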