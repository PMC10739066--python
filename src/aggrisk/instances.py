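"""Decision instances: features + future labels every 15 seconds.

An instance at time ``t`` pairs the feature vector of the past window
``(t - tau_p, t]`` with labels describing the future horizon
``(t, t + tau_f]``: the combined (CMB) label is 1 iff any episode of any
behavior has its onset strictly after ``t`` and no later than
``t + tau_f``; the multiclass target is one such indicator per behavior
(multi-label, because behaviors can co-occur within a horizon).

Augmented feature vectors (AFVs) add two recency covariates: the number of
episode anchors in the past window and the (log1p, capped) time since the
most recent anchor.  Anchors are episode onsets in the onset scenario and
episode offsets in the offset scenario; the offset scenario additionally
removes instances whose decision time falls inside an episode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .e4_io import BEHAVIORS, EpisodeAnnotation, SessionRecording
from .features import FeatureConfig, feature_names, feature_table

logger = logging.getLogger(__name__)

STEP_S = 15.0
TIME_SINCE_CAP_S = 3600.0

AUG_COLS = ["recent_count", "time_since_last"]
LABEL_COLS = ["label_sib", "label_ed", "label_ato", "label_cmb"]
META_COLS = ["participant", "session", "t", "imputed"]


@dataclass(frozen=True)
class LabelConfig:
    """Labeling geometry and target definition.

    ``tau_f`` (s) is the prediction horizon; ``scenario`` anchors the
    recency covariates to onsets or offsets (the latter also drops
    within-episode instances); ``augmented`` switches FV -> AFV.
    """

    tau_f: float = 60.0
    step_s: float = STEP_S
    target: str = "cmb"  # "cmb" or "multiclass"
    scenario: str = "onset"  # "onset" or "offset"
    augmented: bool = False

    def __post_init__(self) -> None:
        if self.target not in ("cmb", "multiclass"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.scenario not in ("onset", "offset"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        n = self.tau_f / self.step_s
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("step_s must divide tau_f")


def label_instant(
    annotations: list[EpisodeAnnotation], t: float, tau_f: float
) -> dict[str, int]:
    """Per-behavior and combined labels for the horizon ``(t, t + tau_f]``."""
    labels = {b: 0 for b in BEHAVIORS}
    for ann in annotations:
        if t < ann.onset_s <= t + tau_f:
            labels[ann.behavior] = 1
    return {
        "label_sib": labels["SIB"],
        "label_ed": labels["ED"],
        "label_ato": labels["ATO"],
        "label_cmb": int(any(labels.values())),
    }


def augment(
    annotations: list[EpisodeAnnotation],
    t: float,
    tau_p: float,
    scenario: str = "onset",
) -> tuple[float, float]:
    """Recency covariates at ``t``: (recent_count, log1p time since last).

    ``recent_count`` counts anchors in ``(t - tau_p, t]``;
    ``time_since_last`` is ``log1p(min(t - last_anchor, 3600))`` with the
    cap value used when no anchor precedes ``t``.
    """
    anchors = np.array(
        [a.onset_s if scenario == "onset" else a.offset_s for a in annotations]
    )
    recent = int(np.sum((anchors > t - tau_p) & (anchors <= t))) if anchors.size else 0
    past = anchors[anchors <= t] if anchors.size else anchors
    raw = (t - past.max()) if past.size else TIME_SINCE_CAP_S
    return float(recent), float(np.log1p(min(raw, TIME_SINCE_CAP_S)))


def decision_times(duration_s: float, tau_p: float, tau_f: float) -> np.ndarray:
    """The 15-s decision grid ``t = tau_p, tau_p + 15, ... <= duration - tau_f``."""
    last = duration_s - tau_f
    if last < tau_p - 1e-9:
        return np.array([])
    n = int(np.floor((last - tau_p) / STEP_S + 1e-9)) + 1
    return tau_p + STEP_S * np.arange(n)


def build_instances(
    rec: SessionRecording,
    annotations: list[EpisodeAnnotation],
    feat_cfg: FeatureConfig,
    label_cfg: LabelConfig,
) -> pd.DataFrame:
    """All labeled instances of one session as a wide DataFrame.

    Columns: metadata, the 22 window features (forward-filled within the
    session where a statistic was undefined), both recency covariates,
    and all four label columns.  A session shorter than
    ``tau_p + tau_f`` yields an empty frame with a warning.
    """
    times = decision_times(rec.duration_s, feat_cfg.tau_p, label_cfg.tau_f)
    cols = META_COLS + feature_names(feat_cfg) + AUG_COLS + LABEL_COLS
    if times.size == 0:
        logger.warning(
            "session %s/%s shorter than tau_p + tau_f; no instances",
            rec.participant_id, rec.session_id,
        )
        return pd.DataFrame(columns=cols)
    if label_cfg.scenario == "offset":
        keep = np.ones(times.size, dtype=bool)
        for ann in annotations:
            keep &= ~((times >= ann.onset_s) & (times <= ann.offset_s))
        times = times[keep]
        if times.size == 0:
            return pd.DataFrame(columns=cols)

    df = feature_table(rec, times, feat_cfg)
    feats = feature_names(feat_cfg)
    df[feats] = df[feats].ffill()

    aug = np.array(
        [augment(annotations, t, feat_cfg.tau_p, label_cfg.scenario) for t in times]
    )
    df[AUG_COLS[0]] = aug[:, 0]
    df[AUG_COLS[1]] = aug[:, 1]
    labels = pd.DataFrame(
        [label_instant(annotations, t, label_cfg.tau_f) for t in times]
    )
    for c in LABEL_COLS:
        df[c] = labels[c].to_numpy()
    return df[cols]


def build_instance_table(
    dataset, feat_cfg: FeatureConfig, label_cfg: LabelConfig
) -> pd.DataFrame:
    """Concatenate :func:`build_instances` over every session of a dataset
    (any object exposing ``sessions()`` yielding (recording, annotations))."""
    frames = [
        build_instances(rec, anns, feat_cfg, label_cfg)
        for rec, anns in dataset.sessions()
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(
            columns=META_COLS + feature_names(feat_cfg) + AUG_COLS + LABEL_COLS
        )
    return pd.concat(frames, ignore_index=True)


def predictor_columns(feat_cfg: FeatureConfig, label_cfg: LabelConfig) -> list[str]:
    """The model input columns implied by the configuration (FV or AFV)."""
    cols = feature_names(feat_cfg)
    if label_cfg.augmented:
        cols = cols + AUG_COLS
    return cols


def target_columns(label_cfg: LabelConfig) -> list[str]:
    if label_cfg.target == "cmb":
        return ["label_cmb"]
    return ["label_sib", "label_ed", "label_ato"]
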