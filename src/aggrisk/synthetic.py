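"""Synthetic multi-participant E4-style datasets with annotated episodes.

The generator emulates the structure of a naturalistic inpatient observation
corpus: participants contribute several sessions; aggressive-behavior
episodes (SIB / ED / ATO) arrive as a self-exciting (Hawkes) point process so
that episodes cluster in time and recency carries signal; episode durations
are log-normal with behavior-specific medians; and each episode is preceded
by a configurable autonomic arousal ramp expressed in the blood-volume-pulse
(heart-rate increase) and electrodermal (skin-conductance-response rate
increase) channels, with movement bursts in the accelerometer during the
episode itself.

Setting the arousal effects to zero and the self-excitation to zero yields a
null corpus in which no feature of the preceding window is informative about
upcoming episodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .e4_io import (
    BEHAVIORS,
    ChannelSeries,
    Dataset,
    EpisodeAnnotation,
    SessionRecording,
    write_annotations,
    write_manifest,
    write_session,
)

logger = logging.getLogger(__name__)

INTENSITY_CLASSES = ("low", "mid", "high")

_EPOCH0 = 1_600_000_000.0  # arbitrary absolute anchor for synthetic sessions


@dataclass
class PopulationConfig:
    """Who is observed and for how long.

    Defaults mirror the corpus scale the generator emulates: a median of
    5 sessions per participant and a median session duration of 4.46 h,
    both log-normal across participants/sessions.  ``sessions_fixed`` /
    ``duration_fixed_s`` pin the draws for small deterministic presets.
    """

    n_participants: int = 10
    seed: int = 0
    sessions_median: float = 5.0
    sessions_sigma: float = 0.6
    sessions_fixed: int | None = None
    duration_median_s: float = 4.46 * 3600.0
    duration_sigma: float = 1.0
    duration_fixed_s: float | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


@dataclass
class EpisodeProcessConfig:
    """Self-exciting episode arrival process and episode attributes.

    Onsets follow intensity ``lambda(t) = mu + sum_i alpha*exp(-beta*(t-t_i))``
    with ``mu = base_rate_per_h / 3600``.  Stability requires
    ``excitation_jump < excitation_decay`` (branching ratio < 1).
    ``behavior_mix`` defaults to the corpus mixture 59.8% SIB / 31.0% ED /
    9.3% ATO and ``duration_medians_s`` to the corpus medians
    (1.97 / 10.09 / 2.31 s), log-normal with ``duration_sigma``.
    """

    base_rate_per_h: float = 3.0
    excitation_jump: float = 1.0 / 200.0  # alpha, 1/s (branching ratio 0.3)
    excitation_decay: float = 1.0 / 60.0  # beta, 1/s: re-escalation risk fades in ~1 min
    behavior_mix: tuple[float, float, float] = (0.598, 0.310, 0.093)
    duration_medians_s: tuple[float, float, float] = (1.97, 10.09, 2.31)
    duration_sigma: float = 1.0
    intensity_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    #: SD (log scale) of a per-participant episode-rate multiplier; the
    #: emulated corpus is extremely skewed (episode counts per participant
    #: range 0 to >1000), which a shared rate cannot reproduce.  Kept 0 in
    #: the evaluation presets so every participant contributes positives.
    rate_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.excitation_jump < 0 or self.excitation_decay <= 0:
            raise ValueError("excitation_jump >= 0 and excitation_decay > 0 required")
        if self.excitation_jump > 0 and self.excitation_jump >= self.excitation_decay:
            raise ValueError(
                "explosive self-exciting process: excitation_jump must be "
                "< excitation_decay (branching ratio < 1)"
            )
        s = sum(self.behavior_mix)
        if abs(s - 1.0) > 5e-3:  # printed percentages round to ~0.1%
            raise ValueError("behavior_mix must sum to 1")
        self.behavior_mix = tuple(p / s for p in self.behavior_mix)
        if any(m <= 0 for m in self.duration_medians_s):
            raise ValueError("duration medians must be positive")


@dataclass
class ArousalConfig:
    """Pre-onset autonomic arousal and channel noise levels.

    The ramp rises linearly from 0 to 1 over the ``ramp_length_s`` seconds
    before each onset and relaxes exponentially (30 s constant) afterwards.
    At full ramp, heart rate is elevated by ``hr_effect_bpm`` and the
    skin-conductance-response (SCR) arrival rate is multiplied by
    ``scr_rate_effect``.  ``hr_effect_bpm = 0`` and ``scr_rate_effect = 1``
    is the null mode.  ``coupling_sd`` is the SD (log scale) of independent
    per-participant multiplicative effects on the two arousal channels;
    ``intensity_arousal_scale`` multiplies both effects per episode
    intensity class, letting movement intensity correlate with arousal.
    """

    ramp_length_s: float = 180.0
    hr_effect_bpm: float = 15.0
    scr_rate_effect: float = 3.0
    coupling_sd: float = 0.0
    intensity_arousal_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    post_onset_decay_s: float = 30.0

    # cardiovascular channel
    hr_base_bpm: float = 80.0
    hr_base_sd_bpm: float = 5.0  # between participants
    hr_wander_sd_bpm: float = 3.0  # slow within-session wander
    hrv_sd_bpm: float = 2.0  # fast beat-to-beat variability
    bvp_noise: float = 0.1

    # electrodermal channel
    scr_base_rate_per_min: float = 2.0
    scr_amp_median_us: float = 0.3
    scr_amp_sigma: float = 0.5
    eda_tonic_base_us: float = 1.0
    eda_drift_sd_us: float = 0.08
    eda_noise_us: float = 0.001  # E4-scale quantization/measurement noise

    # movement channel
    acc_noise_g: float = 0.02
    acc_drift_sd_g: float = 0.05
    episode_move_sd_g: tuple[float, float, float] = (0.15, 0.45, 1.35)
    ambient_burst_rate_per_min: float = 0.5
    ambient_burst_sd_g: float = 0.1
    ambient_burst_dur_s: float = 2.0

    def __post_init__(self) -> None:
        if self.ramp_length_s < 0:
            raise ValueError("ramp_length_s must be >= 0")
        if self.hr_effect_bpm < 0 or self.scr_rate_effect < 0:
            raise ValueError("arousal effects must be >= 0")

    @classmethod
    def null(cls, **kw) -> "ArousalConfig":
        """Arousal-free configuration: pre-onset windows carry no signal."""
        return cls(hr_effect_bpm=0.0, scr_rate_effect=1.0, **kw)


@dataclass(frozen=True)
class Episode:
    """A generated episode with its synthesis ground truth."""

    onset_s: float
    behavior: str
    duration_s: float
    intensity: str  # generator truth, one of INTENSITY_CLASSES

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    def to_annotation(self, participant_id: str, session_id: str) -> EpisodeAnnotation:
        return EpisodeAnnotation(
            participant_id, session_id, self.behavior, self.onset_s, self.offset_s
        )


def simulate_episode_times(
    config: EpisodeProcessConfig, duration_s: float, rng: np.random.Generator
) -> list[Episode]:
    """Draw episodes on ``[0, duration_s)`` from the self-exciting process.

    Uses Ogata thinning with the exponential-kernel recursion.  Behaviors
    are i.i.d. from ``behavior_mix``; durations are log-normal with the
    per-behavior medians, truncated at the session end; overlapping
    same-behavior episodes are merged.
    """
    mu = config.base_rate_per_h / 3600.0
    alpha, beta = config.excitation_jump, config.excitation_decay
    t, excitation = 0.0, 0.0
    onsets: list[float] = []
    while True:
        lam_bar = mu + excitation
        if lam_bar <= 0:
            break
        w = rng.exponential(1.0 / lam_bar)
        t += w
        if t >= duration_s:
            break
        excitation *= np.exp(-beta * w)
        if rng.uniform(0, lam_bar) <= mu + excitation:
            onsets.append(t)
            excitation += alpha

    episodes: list[Episode] = []
    behavior_idx = rng.choice(3, size=len(onsets), p=list(config.behavior_mix))
    intensity_idx = rng.choice(3, size=len(onsets), p=list(config.intensity_mix))
    for onset, bi, ii in zip(onsets, behavior_idx, intensity_idx):
        median = config.duration_medians_s[bi]
        dur = float(
            np.exp(np.log(median) + config.duration_sigma * rng.standard_normal())
        )
        dur = min(dur, duration_s - onset)
        if dur <= 0:
            continue
        episodes.append(
            Episode(float(onset), BEHAVIORS[bi], dur, INTENSITY_CLASSES[ii])
        )
    return _merge_same_behavior(episodes)


def _merge_same_behavior(episodes: list[Episode]) -> list[Episode]:
    merged: list[Episode] = []
    for behavior in BEHAVIORS:
        eps = sorted(
            (e for e in episodes if e.behavior == behavior), key=lambda e: e.onset_s
        )
        for ep in eps:
            if merged and merged[-1].behavior == behavior and ep.onset_s <= merged[-1].offset_s:
                prev = merged.pop()
                ep = Episode(
                    prev.onset_s,
                    behavior,
                    max(prev.offset_s, ep.offset_s) - prev.onset_s,
                    # keep the more intense label on merge
                    max(prev.intensity, ep.intensity, key=INTENSITY_CLASSES.index),
                )
            merged.append(ep)
    merged.sort(key=lambda e: e.onset_s)
    return merged


def _smooth_noise(n: int, dt: float, tau_s: float, sd: float, rng) -> np.ndarray:
    """Stationary Gaussian noise with correlation time ~tau_s and unit-true SD."""
    x = rng.standard_normal(n)
    sigma = max(tau_s / dt, 1e-6)
    x = gaussian_filter1d(x, sigma, mode="reflect")
    s = x.std()
    return x * (sd / s) if s > 0 else x * 0.0


def _ramp_profile(
    episodes: list[Episode],
    times: np.ndarray,
    ramp_s: float,
    decay_s: float,
    scale: dict[str, float],
) -> np.ndarray:
    """Combined arousal ramp: linear 0->1 over the ramp before each onset,
    exponential relaxation after, combined across episodes by max."""
    ramp = np.zeros_like(times)
    if ramp_s <= 0:
        return ramp
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    for ep in episodes:
        s = scale.get(ep.intensity, 1.0)
        if s <= 0:
            continue
        lo = max(ep.onset_s - ramp_s, times[0])
        hi = min(ep.onset_s + 5 * decay_s, times[-1])
        i0, i1 = int(lo / dt), int(hi / dt) + 1
        tt = times[i0:i1]
        seg = np.where(
            tt <= ep.onset_s,
            np.clip(1.0 - (ep.onset_s - tt) / ramp_s, 0.0, 1.0),
            np.exp(-(tt - ep.onset_s) / max(decay_s, 1e-9)),
        )
        np.maximum(ramp[i0:i1], s * seg, out=ramp[i0:i1])
    return ramp


def synthesize_signals(
    episodes: list[Episode],
    arousal: ArousalConfig,
    duration_s: float,
    rng: np.random.Generator,
    participant_id: str = "p",
    session_id: str = "s",
    hr_base_bpm: float | None = None,
    coupling: tuple[float, float] = (1.0, 1.0),
    start_epoch: float = _EPOCH0,
) -> SessionRecording:
    """Render BVP (64 Hz), EDA (4 Hz) and ACC (32 Hz) for one session.

    ``coupling`` is the per-participant multiplicative effect on the
    (heart-rate, SCR-rate) arousal channels.  Rendering is deterministic
    given ``rng`` state.
    """
    if arousal.ramp_length_s > duration_s:
        raise ValueError("arousal ramp longer than the session")
    c_hr, c_scr = coupling
    hr_base = arousal.hr_base_bpm if hr_base_bpm is None else hr_base_bpm
    scale = dict(zip(INTENSITY_CLASSES, arousal.intensity_arousal_scale))

    # --- common 4 Hz arousal/ramp grid -------------------------------------
    fs_g = 4.0
    n_g = int(round(duration_s * fs_g))
    t_g = np.arange(n_g) / fs_g
    ramp = _ramp_profile(
        episodes, t_g, arousal.ramp_length_s, arousal.post_onset_decay_s, scale
    )

    # --- BVP at 64 Hz -------------------------------------------------------
    fs_b = 64.0
    n_b = int(round(duration_s * fs_b))
    t_b = np.arange(n_b) / fs_b
    hr_g = (
        hr_base
        + arousal.hr_effect_bpm * c_hr * ramp
        + _smooth_noise(n_g, 1 / fs_g, 60.0, arousal.hr_wander_sd_bpm, rng)
        + _smooth_noise(n_g, 1 / fs_g, 1.0, arousal.hrv_sd_bpm, rng)
    )
    hr_b = np.interp(t_b, t_g, np.clip(hr_g, 30.0, 200.0))
    phase = np.cumsum(hr_b / 60.0) / fs_b
    bvp = (
        -np.cos(2 * np.pi * phase)
        + 0.3 * np.cos(4 * np.pi * phase + 0.5)
        + arousal.bvp_noise * rng.standard_normal(n_b)
    )

    # --- EDA at 4 Hz ----------------------------------------------------------
    tonic = (
        arousal.eda_tonic_base_us * np.exp(0.3 * rng.standard_normal())
        + _smooth_noise(n_g, 1 / fs_g, 120.0, arousal.eda_drift_sd_us, rng)
    )
    scr_gain = 1.0 + (arousal.scr_rate_effect - 1.0) * c_scr * ramp
    scr_rate = arousal.scr_base_rate_per_min / 60.0 * np.clip(scr_gain, 0.0, None)
    fires = rng.uniform(size=n_g) < scr_rate / fs_g
    phasic = np.zeros(n_g)
    if fires.any():
        k_t = np.arange(int(30 * fs_g)) / fs_g
        kernel = np.exp(-k_t / 4.0) - np.exp(-k_t / 1.0)
        kernel /= kernel.max()
        amps = np.exp(
            np.log(arousal.scr_amp_median_us)
            + arousal.scr_amp_sigma * rng.standard_normal(int(fires.sum()))
        )
        for i, a in zip(np.flatnonzero(fires), amps):
            j = min(i + len(kernel), n_g)
            phasic[i:j] += a * kernel[: j - i]
    eda = np.clip(
        tonic + phasic + arousal.eda_noise_us * rng.standard_normal(n_g), 0.0, None
    )

    # --- ACC at 32 Hz ---------------------------------------------------------
    fs_a = 32.0
    n_a = int(round(duration_s * fs_a))
    t_a = np.arange(n_a) / fs_a
    acc = np.empty((n_a, 3))
    gravity = np.array([0.0, 0.0, 1.0])
    move_sd = dict(zip(INTENSITY_CLASSES, arousal.episode_move_sd_g))
    for ax in range(3):
        drift_g = _smooth_noise(n_g, 1 / fs_g, 30.0, arousal.acc_drift_sd_g, rng)
        acc[:, ax] = (
            gravity[ax]
            + np.interp(t_a, t_g, drift_g)
            + arousal.acc_noise_g * rng.standard_normal(n_a)
        )
    for ep in episodes:  # movement burst during the episode
        i0 = int(ep.onset_s * fs_a)
        i1 = min(int(np.ceil(ep.offset_s * fs_a)), n_a)
        if i1 > i0:
            acc[i0:i1] += move_sd[ep.intensity] * rng.standard_normal((i1 - i0, 3))
    n_amb = rng.poisson(arousal.ambient_burst_rate_per_min * duration_s / 60.0)
    for t0 in rng.uniform(0, duration_s, size=n_amb):  # benign everyday movement
        i0 = int(t0 * fs_a)
        i1 = min(i0 + int(arousal.ambient_burst_dur_s * fs_a), n_a)
        acc[i0:i1] += arousal.ambient_burst_sd_g * rng.standard_normal((i1 - i0, 3))
    # quantize to the E4's 1/64-g integer grid so in-memory == round-tripped
    acc = np.round(acc * 64.0) / 64.0

    channels = {
        "bvp": ChannelSeries("bvp", start_epoch, fs_b, bvp),
        "eda": ChannelSeries("eda", start_epoch, fs_g, eda),
        "acc": ChannelSeries("acc", start_epoch, fs_a, acc),
    }
    return SessionRecording(participant_id, session_id, channels)


@dataclass
class SyntheticSession:
    recording: SessionRecording
    episodes: list[Episode]

    @property
    def annotations(self) -> list[EpisodeAnnotation]:
        rec = self.recording
        return [
            e.to_annotation(rec.participant_id, rec.session_id) for e in self.episodes
        ]


@dataclass
class SyntheticDataset:
    """In-memory dataset: the same surface as :class:`aggrisk.e4_io.Dataset`."""

    sessions_list: list[SyntheticSession] = field(default_factory=list)

    @property
    def annotations(self) -> list[EpisodeAnnotation]:
        return [a for s in self.sessions_list for a in s.annotations]

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "participant": s.recording.participant_id,
                "session": s.recording.session_id,
                "bundle": f"{s.recording.participant_id}/{s.recording.session_id}",
            }
            for s in self.sessions_list
        ]
        return pd.DataFrame(rows, columns=["participant", "session", "bundle"])

    def sessions(self):
        for s in self.sessions_list:
            yield s.recording, s.annotations

    def episode_truth(self) -> pd.DataFrame:
        """Ground-truth episode table including the generator's intensity class."""
        rows = []
        for s in self.sessions_list:
            for e in s.episodes:
                rows.append(
                    {
                        "participant": s.recording.participant_id,
                        "session": s.recording.session_id,
                        "behavior": e.behavior,
                        "onset_s": e.onset_s,
                        "offset_s": e.offset_s,
                        "intensity": e.intensity,
                    }
                )
        return pd.DataFrame(rows)


def generate_sessions(
    pop: PopulationConfig,
    proc: EpisodeProcessConfig | None = None,
    arousal: ArousalConfig | None = None,
) -> SyntheticDataset:
    """Generate the full in-memory dataset; deterministic given ``pop.seed``.

    Per participant, independent log-normal coupling multipliers (SD
    ``arousal.coupling_sd``) modulate the heart-rate and SCR arousal
    channels, and a baseline heart rate is drawn N(hr_base, hr_base_sd).
    """
    proc = proc or EpisodeProcessConfig()
    arousal = arousal or ArousalConfig()
    root_ss = np.random.SeedSequence(pop.seed)
    part_seeds = root_ss.spawn(pop.n_participants)
    dataset = SyntheticDataset()
    for pi, pseed in enumerate(part_seeds):
        prng = np.random.default_rng(pseed)
        pid = f"p{pi + 1:03d}"
        coupling = tuple(
            np.exp(arousal.coupling_sd * prng.standard_normal(2))
        )
        hr_base = arousal.hr_base_bpm + arousal.hr_base_sd_bpm * prng.standard_normal()
        pproc = proc
        if proc.rate_sigma > 0:
            mult = float(np.exp(proc.rate_sigma * prng.standard_normal()))
            pproc = replace(proc, base_rate_per_h=proc.base_rate_per_h * mult)
        if pop.sessions_fixed is not None:
            n_sessions = pop.sessions_fixed
        else:
            n_sessions = max(
                1,
                int(
                    round(
                        np.exp(
                            np.log(pop.sessions_median)
                            + pop.sessions_sigma * prng.standard_normal()
                        )
                    )
                ),
            )
        for si in range(n_sessions):
            srng = prng  # sessions consume the participant stream in order
            if pop.duration_fixed_s is not None:
                dur = pop.duration_fixed_s
            else:
                dur = float(
                    np.exp(
                        np.log(pop.duration_median_s)
                        + pop.duration_sigma * srng.standard_normal()
                    )
                )
                dur = max(dur, 2.0 * arousal.ramp_length_s + 120.0)
            sid = f"s{si + 1:02d}"
            episodes = simulate_episode_times(pproc, dur, srng)
            rec = synthesize_signals(
                episodes,
                arousal,
                dur,
                srng,
                participant_id=pid,
                session_id=sid,
                hr_base_bpm=hr_base,
                coupling=coupling,
                start_epoch=_EPOCH0 + pi * 1e5 + si * 1e4,
            )
            dataset.sessions_list.append(SyntheticSession(rec, episodes))
    return dataset


def generate_dataset(
    pop: PopulationConfig,
    proc: EpisodeProcessConfig | None = None,
    arousal: ArousalConfig | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticDataset | Dataset:
    """Generate a dataset; if ``out_dir`` is given, write bundles,
    ``annotations.csv``, ``manifest.csv`` and ``episode_truth.csv`` there
    and return the re-loadable on-disk :class:`Dataset`."""
    mem = generate_sessions(pop, proc, arousal)
    if out_dir is None:
        return mem
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    for s in mem.sessions_list:
        rec = s.recording
        write_session(rec, root / rec.participant_id / rec.session_id)
    write_annotations(mem.annotations, root / "annotations.csv")
    write_manifest(mem.manifest, root / "manifest.csv")
    mem.episode_truth().to_csv(root / "episode_truth.csv", index=False)
    return Dataset.load(root)


def generate_structure(
    pop: PopulationConfig, proc: EpisodeProcessConfig | None = None
) -> tuple[list[EpisodeAnnotation], pd.DataFrame]:
    """Corpus structure only — annotations plus a session table
    (participant, session, duration_s) — without rendering any signals.

    Useful at full corpus scale (hundreds of observation hours), where
    rendering waveforms would be pointless for descriptive statistics.
    """
    proc = proc or EpisodeProcessConfig()
    root_ss = np.random.SeedSequence(pop.seed)
    annotations: list[EpisodeAnnotation] = []
    sess_rows = []
    for pi, pseed in enumerate(root_ss.spawn(pop.n_participants)):
        prng = np.random.default_rng(pseed)
        pid = f"p{pi + 1:03d}"
        pproc = proc
        if proc.rate_sigma > 0:
            mult = float(np.exp(proc.rate_sigma * prng.standard_normal()))
            pproc = replace(proc, base_rate_per_h=proc.base_rate_per_h * mult)
        if pop.sessions_fixed is not None:
            n_sessions = pop.sessions_fixed
        else:
            n_sessions = max(
                1,
                int(round(np.exp(
                    np.log(pop.sessions_median)
                    + pop.sessions_sigma * prng.standard_normal()
                ))),
            )
        for si in range(n_sessions):
            if pop.duration_fixed_s is not None:
                dur = pop.duration_fixed_s
            else:
                dur = float(np.exp(
                    np.log(pop.duration_median_s)
                    + pop.duration_sigma * prng.standard_normal()
                ))
            sid = f"s{si + 1:02d}"
            sess_rows.append(
                {"participant": pid, "session": sid, "duration_s": dur}
            )
            for ep in simulate_episode_times(pproc, dur, prng):
                annotations.append(ep.to_annotation(pid, sid))
    return annotations, pd.DataFrame(sess_rows)


# ---------------------------------------------------------------------------
# presets

def desk_preset(seed: int = 0) -> PopulationConfig:
    """Small desk-scale preset: 10 participants x 3 sessions x 30 min."""
    return PopulationConfig(
        n_participants=10, seed=seed, sessions_fixed=3, duration_fixed_s=1800.0
    )


def corpus_preset(seed: int = 0) -> PopulationConfig:
    """Full-scale preset mirroring the emulated corpus structure."""
    return PopulationConfig(n_participants=70, seed=seed)


def corpus_process_preset() -> EpisodeProcessConfig:
    """Episode process for corpus-scale structure: a skewed per-participant
    rate (log-SD 1.2 around 0.7/h) reproduces both participant-level median
    episode counts and a corpus-level total in the thousands."""
    return EpisodeProcessConfig(base_rate_per_h=0.7, rate_sigma=1.2)


def scaled_preset(
    seed: int,
    n_participants: int,
    n_sessions: int,
    duration_s: float,
) -> PopulationConfig:
    return PopulationConfig(
        n_participants=n_participants,
        seed=seed,
        sessions_fixed=n_sessions,
        duration_fixed_s=duration_s,
    )
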