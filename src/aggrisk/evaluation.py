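"""Validation machinery: AUROC, grouped splits, and the experiment harness.

Three split schemes guard against the leakage modes of sliding-window
pipelines:

* **SS** (session split): within each session the chronologically first 80%
  of decision instants train, the last 20% test, with a purge gap of
  ``tau_p + tau_f`` seconds removed from the training side of the boundary
  so no training instance's label horizon overlaps a test instance's
  feature window (a train instance at ``t_tr`` and test instance at
  ``t_te`` interact iff ``t_te - t_tr < tau_p + tau_f``).
* **LIO** (leave-individuals-out): k-fold over participants, repeated with
  reseeded shuffles — external validity across people.
* **LSO** (leave-sessions-out): per participant, k-fold over that
  participant's sessions — external validity across days within a person.

The seven-experiment grid crosses population (PM) vs person-dependent (PDM)
model scopes with these schemes, binary combined (CMB) vs per-behavior
multi-label targets, physiology-only (FV) vs recency-augmented (AFV)
predictors in onset/offset scenarios, and movement-intensity strata.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score

from .e4_io import BEHAVIORS, EpisodeAnnotation
from .features import FeatureConfig, feature_names, feature_table
from .instances import (
    AUG_COLS,
    LABEL_COLS,
    LabelConfig,
    augment,
    decision_times,
    label_instant,
)
from .models import FittedModel, ModelSpec, SingleClassError, train

logger = logging.getLogger(__name__)

INTENSITY_ORDER = ("low", "mid", "high")

#: experiment id -> (model scope, split scheme, target)
EXPERIMENTS = {
    1: ("pm", "ss", "cmb"),
    2: ("pdm", "ss", "cmb"),
    3: ("pm", "lio", "cmb"),
    4: ("pdm", "lso", "cmb"),
    5: ("pm", "lio", "multiclass"),
    6: ("pdm", "lso", "multiclass"),
    7: ("pm", "ss", "intensity"),
}

SCENARIOS = ("fv", "afv_onset", "afv_offset")


# ---------------------------------------------------------------------------
# AUROC and confidence intervals

def auroc(scores, labels) -> float:
    """Rank-based AUROC (ties count 0.5); NaN when a class is absent."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        logger.warning("AUROC undefined: single class present")
        return float("nan")
    return float(roc_auc_score(labels, scores))


def t_ci95(values: np.ndarray) -> tuple[float, float, float]:
    """(mean, low, high): t-interval over fold-level values (NaNs dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return (float("nan"),) * 3
    m = float(v.mean())
    if v.size == 1:
        return m, float("nan"), float("nan")
    half = stats.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return m, m - float(half), m + float(half)


def bootstrap_auroc_ci(
    scores, labels, n_boot: int = 200, seed: int = 0
) -> tuple[float, float, float]:
    """(auroc, low, high): stratified bootstrap percentile interval."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = auroc(scores, labels)
    pos, neg = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        return point, float("nan"), float("nan")
    vals = []
    for _ in range(n_boot):
        bp = rng.choice(pos, pos.size)
        bn = rng.choice(neg, neg.size)
        idx = np.concatenate([bp, bn])
        vals.append(auroc(scores[idx], labels[idx]))
    lo, hi = np.nanpercentile(vals, [2.5, 97.5])
    return point, float(lo), float(hi)


# ---------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class SplitPlan:
    """How to partition instances into train/test groups.

    ``purge_gap_s`` applies to the SS scheme only and should normally be
    ``tau_p + tau_f``; set ``purge_gap_s = 0`` for a literal 80/20 split
    with no boundary purge.
    """

    scheme: str = "ss"
    k: int = 5
    repetitions: int = 5
    seed: int = 0
    purge_gap_s: float = 0.0
    train_frac: float = 0.8

    def __post_init__(self) -> None:
        if self.scheme not in ("ss", "lio", "lso"):
            raise ValueError(f"unknown split scheme {self.scheme!r}")


@dataclass
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray
    meta: dict = field(default_factory=dict)


def make_splits(instances: pd.DataFrame, plan: SplitPlan) -> list[Split]:
    """Build train/test index-array pairs over an instance table.

    SS yields one split; LIO yields ``k x repetitions`` splits partitioning
    participants per repetition; LSO yields per-participant session folds
    (participants with fewer than 2 sessions are excluded with a warning).
    """
    df = instances
    if plan.scheme == "ss":
        train_parts, test_parts = [], []
        for _, g in df.groupby(["participant", "session"], sort=False):
            t = g["t"].to_numpy()
            lo, hi = t.min(), t.max()
            cutoff = lo + plan.train_frac * (hi - lo)
            train_parts.append(g.index[t <= cutoff - plan.purge_gap_s])
            test_parts.append(g.index[t > cutoff])
        return [
            Split(
                np.concatenate([p.to_numpy() for p in train_parts]),
                np.concatenate([p.to_numpy() for p in test_parts]),
                {"scheme": "ss", "rep": 0, "fold": 0},
            )
        ]

    if plan.scheme == "lio":
        participants = np.array(sorted(df["participant"].unique()))
        if participants.size < plan.k:
            raise ValueError(
                f"LIO needs >= k={plan.k} participants, got {participants.size}"
            )
        splits = []
        for rep in range(plan.repetitions):
            rng = np.random.default_rng(plan.seed + rep)
            order = rng.permutation(participants)
            for fold, test_group in enumerate(np.array_split(order, plan.k)):
                mask = df["participant"].isin(test_group).to_numpy()
                splits.append(
                    Split(
                        df.index[~mask].to_numpy(),
                        df.index[mask].to_numpy(),
                        {"scheme": "lio", "rep": rep, "fold": fold,
                         "test_participants": list(test_group)},
                    )
                )
        return splits

    # lso: per participant, k-fold over sessions
    splits = []
    for pid, g in df.groupby("participant", sort=True):
        sessions = np.array(sorted(g["session"].unique()))
        if sessions.size < 2:
            logger.warning("LSO: excluding participant %s with < 2 sessions", pid)
            continue
        k_p = min(plan.k, sessions.size)
        for rep in range(plan.repetitions):
            rng = np.random.default_rng(plan.seed + rep)
            order = rng.permutation(sessions)
            for fold, test_group in enumerate(np.array_split(order, k_p)):
                mask = g["session"].isin(test_group).to_numpy()
                splits.append(
                    Split(
                        g.index[~mask].to_numpy(),
                        g.index[mask].to_numpy(),
                        {"scheme": "lso", "rep": rep, "fold": fold,
                         "participant": pid},
                    )
                )
    return splits


# ---------------------------------------------------------------------------
# batched instance preparation (shared features across tau_f and scenarios)

def prepare_instances(
    dataset, tau_p: float, tau_fs: tuple[float, ...]
) -> pd.DataFrame:
    """One wide table reused across horizons and scenarios.

    Features depend on ``tau_p`` only, recency covariates on the scenario,
    and labels on ``tau_f``; computing them together avoids re-extracting
    features per grid cell.  Columns: features; ``recent_count_onset`` etc.;
    ``label_<cls>_<tau_f>``; ``inside_episode``; ``session_duration``.
    """
    min_tau_f = min(tau_fs)
    feat_cfg = FeatureConfig(tau_p=tau_p)
    frames = []
    for rec, anns in dataset.sessions():
        times = decision_times(rec.duration_s, tau_p, min_tau_f)
        if times.size == 0:
            logger.warning(
                "session %s/%s too short for tau_p=%s + tau_f=%s",
                rec.participant_id, rec.session_id, tau_p, min_tau_f,
            )
            continue
        df = feature_table(rec, times, feat_cfg)
        fcols = feature_names(feat_cfg)
        df[fcols] = df[fcols].ffill()
        for scen in ("onset", "offset"):
            aug = np.array([augment(anns, t, tau_p, scen) for t in times])
            df[f"recent_count_{scen}"] = aug[:, 0]
            df[f"time_since_last_{scen}"] = aug[:, 1]
        inside = np.zeros(times.size, dtype=bool)
        for a in anns:
            inside |= (times >= a.onset_s) & (times <= a.offset_s)
        df["inside_episode"] = inside
        for tau_f in tau_fs:
            labels = pd.DataFrame([label_instant(anns, t, tau_f) for t in times])
            for c in LABEL_COLS:
                df[f"{c}_{int(tau_f)}"] = labels[c].to_numpy()
        df["session_duration"] = rec.duration_s
        frames.append(df)
    if not frames:
        raise ValueError("dataset produced no instances")
    return pd.concat(frames, ignore_index=True)


def scenario_view(
    prepared: pd.DataFrame, tau_p: float, tau_f: float, scenario: str
) -> tuple[pd.DataFrame, list[str]]:
    """Materialize one (tau_f, scenario) cell from a prepared table.

    Returns the instance table with standard label/augmentation column
    names and the predictor column list for the scenario (``fv``,
    ``afv_onset`` or ``afv_offset``).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    anchor = "offset" if scenario == "afv_offset" else "onset"
    df = prepared[prepared["t"] <= prepared["session_duration"] - tau_f + 1e-9]
    if scenario == "afv_offset":
        df = df[~df["inside_episode"]]
    df = df.copy()
    df["recent_count"] = df[f"recent_count_{anchor}"]
    df["time_since_last"] = df[f"time_since_last_{anchor}"]
    for c in LABEL_COLS:
        df[c] = df[f"{c}_{int(tau_f)}"]
    predictors = list(feature_names())
    if scenario != "fv":
        predictors += AUG_COLS
    return df.reset_index(drop=True), predictors


# ---------------------------------------------------------------------------
# experiment harness

def _target_cols(target: str) -> list[str]:
    return ["label_cmb"] if target == "cmb" else ["label_sib", "label_ed", "label_ato"]


def _eval_split(
    spec: ModelSpec,
    df: pd.DataFrame,
    predictors: list[str],
    targets: list[str],
    split: Split,
    min_train: int = 2,
) -> list[dict]:
    """Train on a split and return one row per target class."""
    tr, te = df.loc[split.train_idx], df.loc[split.test_idx]
    rows = []
    base = {"rep": split.meta.get("rep", 0), "fold": split.meta.get("fold", 0),
            "unit": split.meta.get("participant", "pm")}
    if len(tr) < min_train or len(te) == 0:
        for tgt in targets:
            rows.append({**base, "target": tgt, "auroc": np.nan,
                         "n_test": len(te), "n_pos": 0, "note": "empty_split"})
        return rows
    groups = (tr["participant"] + "/" + tr["session"]).to_numpy()
    for tgt in targets:
        try:
            model = train(spec, tr, tr[[tgt]], feature_names=predictors, groups=groups)
        except SingleClassError:
            rows.append({**base, "target": tgt, "auroc": np.nan,
                         "n_test": len(te),
                         "n_pos": int(te[tgt].sum()), "note": "single_class_train"})
            continue
        scores = model.score_one(te)
        rows.append({
            **base,
            "target": tgt,
            "auroc": auroc(scores, te[tgt]),
            "n_test": len(te),
            "n_pos": int(te[tgt].sum()),
            "note": "",
        })
    return rows


def run_experiment(
    exp_id: int,
    dataset,
    families: tuple[str, ...] = ("lr",),
    tau_grid: tuple[tuple[float, float], ...] = ((180.0, 60.0),),
    scenarios: tuple[str, ...] = ("fv", "afv_onset"),
    k: int = 5,
    repetitions: int = 5,
    seed: int = 0,
    purge: bool = True,
    min_pdm_instances: int = 50,
) -> pd.DataFrame:
    """Run one experiment over the model x tau x scenario grid.

    Returns a tidy frame with one row per (cell, fold, target); infeasible
    cells are recorded with ``auroc = NaN`` and a reason in ``note``,
    never silently dropped.
    """
    if exp_id not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {exp_id}; valid ids: {sorted(EXPERIMENTS)}")
    scope, scheme, target = EXPERIMENTS[exp_id]
    rows: list[dict] = []
    tau_ps = sorted({p for p, _ in tau_grid})
    clusters = None
    if target == "intensity":
        clusters = intensity_clusters(dataset, seed=seed)
    for tau_p in tau_ps:
        tau_fs = tuple(sorted({f for p, f in tau_grid if p == tau_p}))
        prepared = prepare_instances(dataset, tau_p, tau_fs)
        for tau_f, scen in itertools.product(tau_fs, scenarios):
            df, predictors = scenario_view(prepared, tau_p, tau_f, scen)
            plan = SplitPlan(
                scheme=scheme, k=k, repetitions=repetitions, seed=seed,
                purge_gap_s=(tau_p + tau_f) if purge else 0.0,
            )
            if target == "intensity":
                cell_rows = _run_intensity_cell(
                    dataset, df, predictors, clusters, tau_f, plan, families, seed
                )
            elif scope == "pm":
                cell_rows = []
                splits = make_splits(df, plan)
                for fam in families:
                    spec = ModelSpec(family=fam, seed=seed)
                    for split in splits:
                        for r in _eval_split(spec, df, predictors,
                                             _target_cols(target), split):
                            cell_rows.append({**r, "family": fam})
            else:  # pdm: fit within each participant
                cell_rows = []
                for pid, g in df.groupby("participant", sort=True):
                    if len(g) < min_pdm_instances:
                        logger.warning("PDM: participant %s has %d < %d instances",
                                       pid, len(g), min_pdm_instances)
                        continue
                    sub_plan = plan
                    try:
                        splits = make_splits(g, sub_plan)
                    except ValueError:
                        continue
                    for fam in families:
                        spec = ModelSpec(family=fam, seed=seed)
                        for split in splits:
                            for r in _eval_split(spec, g, predictors,
                                                 _target_cols(target), split):
                                cell_rows.append({**r, "family": fam, "unit": pid})
            for r in cell_rows:
                r.update({"experiment": exp_id, "tau_p": tau_p, "tau_f": tau_f,
                          "scenario": scen, "scheme": scheme, "scope": scope})
            rows.extend(cell_rows)
    cols = ["experiment", "scope", "scheme", "family", "tau_p", "tau_f",
            "scenario", "target", "unit", "rep", "fold", "n_test", "n_pos",
            "auroc", "note"]
    out = pd.DataFrame(rows)
    return out[cols] if not out.empty else pd.DataFrame(columns=cols)


def _run_intensity_cell(
    dataset, df, predictors, clusters, tau_f, plan, families, seed
) -> list[dict]:
    """Experiment 7: train on the combined label, score test instances per
    movement-intensity cluster, counting only that cluster's episodes as
    positives and excluding instants positive solely for other clusters."""
    by_session: dict[tuple[str, str], pd.DataFrame] = {
        k: g for k, g in clusters.groupby(["participant", "session"])
    }
    cls_labels = {}
    for cls in INTENSITY_ORDER:
        lab = np.zeros(len(df), dtype=int)
        for i, (pid, sid, t) in enumerate(
            zip(df["participant"], df["session"], df["t"])
        ):
            g = by_session.get((pid, sid))
            if g is None:
                continue
            sel = g[g["cluster"] == cls]
            lab[i] = int(((sel["onset_s"] > t) & (sel["onset_s"] <= t + tau_f)).any())
        cls_labels[cls] = lab
    rows = []
    splits = make_splits(df, plan)
    for fam in families:
        spec = ModelSpec(family=fam, seed=seed)
        for split in splits:
            tr = df.loc[split.train_idx]
            te = df.loc[split.test_idx]
            try:
                model = train(
                    spec, tr, tr[["label_cmb"]], feature_names=predictors,
                    groups=(tr["participant"] + "/" + tr["session"]).to_numpy(),
                )
            except SingleClassError:
                continue
            scores_all = model.score_one(df)
            for cls in INTENSITY_ORDER:
                lab = cls_labels[cls]
                te_pos = np.asarray(te.index)
                # score only negatives and this cluster's positives
                mask = (lab[te_pos] == 1) | (df.loc[te_pos, "label_cmb"].to_numpy() == 0)
                idx = te_pos[mask]
                rows.append({
                    "family": fam,
                    "target": f"intensity_{cls}",
                    "rep": split.meta.get("rep", 0),
                    "fold": split.meta.get("fold", 0),
                    "unit": "pm",
                    "auroc": auroc(scores_all[idx], lab[idx]),
                    "n_test": int(idx.size),
                    "n_pos": int(lab[idx].sum()),
                    "note": "",
                })
    return rows


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate fold rows to mean/median/CI95 per experiment cell."""
    keys = ["experiment", "scope", "scheme", "family", "tau_p", "tau_f",
            "scenario", "target"]
    out = []
    for key, g in results.groupby(keys, dropna=False):
        vals = g["auroc"].to_numpy()
        mean, lo, hi = t_ci95(vals)
        out.append(dict(zip(keys, key)) | {
            "n_folds": int(np.sum(~np.isnan(vals))),
            "n_missing": int(np.sum(np.isnan(vals))),
            "mean_auroc": mean,
            "median_auroc": float(np.nanmedian(vals)) if np.any(~np.isnan(vals)) else np.nan,
            "ci95_low": lo,
            "ci95_high": hi,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# movement-intensity clustering (experiment 7 support)

def episode_intensity(rec, ann: EpisodeAnnotation) -> float:
    """Mean deviation of acceleration magnitude from 1 g during the episode."""
    acc = rec.acc
    i0 = int(np.floor(ann.onset_s * acc.rate))
    i1 = max(int(np.ceil(ann.offset_s * acc.rate)), i0 + 1)
    seg = acc.samples[i0:i1]
    if seg.shape[0] == 0:
        return float("nan")
    mag = np.linalg.norm(seg, axis=1)
    return float(np.mean(np.abs(mag - 1.0)))


def intensity_clusters(dataset, seed: int = 0) -> pd.DataFrame:
    """Assign each episode a movement-intensity class (low/mid/high).

    Per-episode intensity is the mean |acceleration magnitude - 1 g| over
    the episode; classes come from 1-D k-means (k = 3, seeded) on the log
    intensity, with cluster centers ordered so labels are monotone.
    """
    rows = []
    for rec, anns in dataset.sessions():
        for a in anns:
            val = episode_intensity(rec, a)
            rows.append({
                "participant": a.participant_id, "session": a.session_id,
                "behavior": a.behavior, "onset_s": a.onset_s,
                "offset_s": a.offset_s, "intensity_value": val,
            })
    if len(rows) < 3:
        raise ValueError("need at least 3 episodes to form intensity clusters")
    df = pd.DataFrame(rows).dropna(subset=["intensity_value"])
    if len(df) < 3:
        raise ValueError("need at least 3 episodes to form intensity clusters")
    x = np.log(df["intensity_value"].to_numpy() + 1e-9).reshape(-1, 1)
    if np.unique(np.round(x, 12)).size < 3:
        raise ValueError("degenerate intensities: fewer than 3 distinct values")
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = {int(order[i]): INTENSITY_ORDER[i] for i in range(3)}
    df = df.reset_index(drop=True)
    df["cluster"] = [remap[int(c)] for c in km.labels_]
    return df


# ---------------------------------------------------------------------------
# test-retest and behavior-property analyses

def test_retest(
    session_aurocs: pd.DataFrame, group_size: int = 3
) -> pd.DataFrame:
    """Median/IQR AUROC over groups of consecutive sessions.

    Input columns: ``participant``, ``session_order`` (0-based chronological
    index within participant) and ``auroc``.  Incomplete trailing groups
    are kept and flagged.
    """
    df = session_aurocs.copy()
    df["group"] = (df["session_order"] // group_size).astype(int)
    out = []
    for grp, g in df.groupby("group"):
        vals = g["auroc"].dropna().to_numpy()
        first, last = grp * group_size + 1, (grp + 1) * group_size
        out.append({
            "group": int(grp),
            "sessions": f"{first}-{last}",
            "n": int(vals.size),
            "median_auroc": float(np.median(vals)) if vals.size else np.nan,
            "iqr_low": float(np.percentile(vals, 25)) if vals.size else np.nan,
            "iqr_high": float(np.percentile(vals, 75)) if vals.size else np.nan,
            "complete": bool((g["session_order"] % group_size).nunique() == group_size),
        })
    return pd.DataFrame(out)


def property_correlations(
    per_participant: pd.DataFrame,
    properties: tuple[str, ...] = (
        "n_sessions", "n_episodes", "mean_episode_duration_s", "total_duration_h",
    ),
    method: str = "spearman",
) -> pd.DataFrame:
    """Rank (or Pearson) correlation of per-participant AUROC with corpus
    properties; constant inputs yield NaN with a flag."""
    if len(per_participant) < 5:
        raise ValueError("need >= 5 participants with defined AUROC")
    fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for prop in properties:
        x = per_participant[prop].to_numpy(dtype=float)
        y = per_participant["auroc"].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append({"property": prop, "rho": np.nan, "p_value": np.nan,
                         "flag": "constant_input"})
            continue
        r = fn(x[ok], y[ok])
        rows.append({"property": prop, "rho": float(r.statistic),
                     "p_value": float(r.pvalue), "flag": ""})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# corpus descriptive statistics

def summarize_counts(n_sib: int, n_ed: int, n_ato: int) -> dict:
    """Episode-count arithmetic: total, percentages and frequency ratios."""
    total = n_sib + n_ed + n_ato
    if total == 0:
        raise ValueError("no episodes")
    out = {
        "total": total,
        "pct_sib": 100.0 * n_sib / total,
        "pct_ed": 100.0 * n_ed / total,
        "pct_ato": 100.0 * n_ato / total,
        "ratio_sib_ed": n_sib / n_ed if n_ed else float("nan"),
        "ratio_sib_ato": n_sib / n_ato if n_ato else float("nan"),
    }
    return out


def attrition_pct(n_enrolled: int, n_excluded: int) -> float:
    """Enrollment attrition as a percentage of those enrolled."""
    if n_enrolled <= 0:
        raise ValueError("n_enrolled must be positive")
    return 100.0 * n_excluded / n_enrolled


def relative_difference_pct(low: float, high: float) -> float:
    """Relative percent difference ``(high - low) / low * 100``."""
    if low == 0:
        raise ValueError("undefined for low == 0")
    return 100.0 * (high - low) / low


def _median_iqr(x: np.ndarray) -> dict:
    if x.size == 0:
        return {"median": np.nan, "iqr_low": np.nan, "iqr_high": np.nan}
    return {
        "median": float(np.median(x)),
        "iqr_low": float(np.percentile(x, 25)),
        "iqr_high": float(np.percentile(x, 75)),
    }


def corpus_summary(dataset, session_durations: pd.DataFrame | None = None) -> dict:
    """Descriptive statistics of a dataset, shaped like a corpus table.

    Returns per-behavior episode counts/percentages/ratios plus
    per-participant medians and IQRs of session count, session duration
    (hours, if durations are obtainable), and per-behavior episode counts
    and durations (seconds).
    """
    anns = dataset.annotations
    manifest = dataset.manifest
    if len(manifest) == 0:
        raise ValueError("empty dataset")
    counts = {b: sum(1 for a in anns if a.behavior == b) for b in BEHAVIORS}
    summary: dict = {"n_participants": manifest["participant"].nunique(),
                     "n_sessions": len(manifest)}
    if sum(counts.values()) > 0:
        summary |= summarize_counts(counts["SIB"], counts["ED"], counts["ATO"])
    summary["counts"] = counts

    per_part_sessions = manifest.groupby("participant")["session"].nunique()
    summary["sessions_per_participant"] = _median_iqr(per_part_sessions.to_numpy(float))

    if session_durations is None:
        try:
            session_durations = pd.DataFrame(
                [
                    {"participant": rec.participant_id, "session": rec.session_id,
                     "duration_s": rec.duration_s}
                    for rec, _ in dataset.sessions()
                ]
            )
        except Exception:
            session_durations = None
    if session_durations is not None and len(session_durations):
        summary["session_duration_h"] = _median_iqr(
            session_durations["duration_s"].to_numpy(float) / 3600.0
        )
        summary["total_hours"] = float(session_durations["duration_s"].sum() / 3600.0)

    participants = manifest["participant"].unique()
    for b in BEHAVIORS:
        eps = [a for a in anns if a.behavior == b]
        per_part = np.array(
            [sum(1 for a in eps if a.participant_id == p) for p in participants],
            dtype=float,
        )
        durs = np.array([a.duration_s for a in eps])
        summary[f"{b.lower()}_episodes_per_participant"] = _median_iqr(per_part)
        summary[f"{b.lower()}_duration_s"] = _median_iqr(durs)
    return summary
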