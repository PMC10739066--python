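"""AUROC machinery, split schemes, experiment harness and corpus statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggrisk.evaluation import (
    EXPERIMENTS,
    SplitPlan,
    attrition_pct,
    auroc,
    corpus_summary,
    intensity_clusters,
    make_splits,
    prepare_instances,
    property_correlations,
    relative_difference_pct,
    run_experiment,
    scenario_view,
    summarize,
    summarize_counts,
    t_ci95,
)
from aggrisk.evaluation import test_retest as retest_by_session_group


def pair_count_auroc(scores, labels):
    """Independent oracle: exhaustive concordant-pair enumeration."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    total = conc = 0.0
    for p in pos:
        for n in neg:
            total += 1
            conc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return conc / total if total else float("nan")


def test_auroc_examples():
    assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert auroc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5
    assert auroc([0.9, 0.4, 0.6, 0.1], [1, 0, 1, 0]) == 1.0
    assert auroc([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0]) == 0.75
    assert np.isnan(auroc([0.1, 0.2], [1, 1]))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    n=st.integers(4, 200),
    seed=st.integers(0, 10_000),
    ties=st.booleans(),
)
def test_auroc_equals_pair_counting(n, seed, ties):
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 5, n).astype(float) if ties else rng.standard_normal(n)
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert auroc(scores, labels) == pytest.approx(pair_count_auroc(scores, labels))


def test_t_ci_contains_mean_and_shrinks():
    m, lo, hi = t_ci95(np.array([0.7, 0.8, 0.9]))
    assert lo <= m <= hi
    m2, lo2, hi2 = t_ci95(np.tile([0.7, 0.8, 0.9], 5))
    assert (hi2 - lo2) < (hi - lo)


# --- splits ---------------------------------------------------------------

def _fake_instances(n_participants=10, n_sessions=3, n_t=40):
    rows = []
    for p in range(n_participants):
        for s in range(n_sessions):
            for i in range(n_t):
                rows.append({
                    "participant": f"p{p:02d}", "session": f"s{s}",
                    "t": 180.0 + 15.0 * i,
                })
    return pd.DataFrame(rows)


def test_ss_split_ratio_and_purge_gap():
    df = _fake_instances(2, 2, 100)
    plan = SplitPlan(scheme="ss", purge_gap_s=240.0)
    (split,) = make_splits(df, plan)
    assert set(split.train_idx).isdisjoint(split.test_idx)
    for _, g in df.groupby(["participant", "session"]):
        t = g["t"].to_numpy()
        cutoff = t.min() + 0.8 * (t.max() - t.min())
        tr_t = df.loc[[i for i in split.train_idx if i in g.index], "t"]
        te_t = df.loc[[i for i in split.test_idx if i in g.index], "t"]
        assert len(te_t) <= np.ceil(0.2 * len(g))
        assert tr_t.max() <= cutoff - 240.0
        assert te_t.min() > cutoff
        # nothing inside the purge gap on the training side
        assert not ((tr_t > cutoff - 240.0) & (tr_t <= cutoff)).any()


def test_lio_partitions_participants():
    df = _fake_instances(10, 2, 10)
    plan = SplitPlan(scheme="lio", k=5, repetitions=5, seed=0)
    splits = make_splits(df, plan)
    assert len(splits) == 25  # 5 folds x 5 repetitions
    for rep in range(5):
        rep_splits = [s for s in splits if s.meta["rep"] == rep]
        test_parts = [set(df.loc[s.test_idx, "participant"]) for s in rep_splits]
        assert all(len(t) == 2 for t in test_parts)
        assert set.union(*test_parts) == set(df["participant"])
        for a in rep_splits:
            assert set(a.train_idx).isdisjoint(a.test_idx)


def test_lso_excludes_single_session_participants(caplog):
    df = pd.concat([
        _fake_instances(3, 3, 10),
        _fake_instances(1, 1, 10).assign(participant="lonely"),
    ], ignore_index=True)
    splits = make_splits(df, SplitPlan(scheme="lso", k=5, repetitions=1, seed=0))
    tested = {p for s in splits for p in df.loc[s.test_idx, "participant"].unique()}
    assert "lonely" not in tested
    for s in splits:
        pid = s.meta["participant"]
        assert (df.loc[s.train_idx, "participant"] == pid).all()
        tr_sess = set(df.loc[s.train_idx, "session"])
        te_sess = set(df.loc[s.test_idx, "session"])
        assert tr_sess.isdisjoint(te_sess)


def test_unknown_scheme_and_experiment_rejected(tiny_dataset):
    with pytest.raises(ValueError):
        SplitPlan(scheme="bogus")
    with pytest.raises(ValueError, match="valid ids"):
        run_experiment(99, tiny_dataset)


# --- harness --------------------------------------------------------------

def test_label_permutation_drives_auroc_to_chance(strong_instances):
    """Permuting labels on a strong-signal corpus must destroy the AUROC —
    the key leakage check for sliding-window pipelines."""
    from aggrisk.models import ModelSpec, train

    df, preds = scenario_view(strong_instances, 180.0, 60.0, "fv")
    rng = np.random.default_rng(0)
    df = df.copy()
    df["label_cmb"] = rng.permutation(df["label_cmb"].to_numpy())
    (split,) = make_splits(df, SplitPlan(scheme="ss", purge_gap_s=240.0))
    tr, te = df.loc[split.train_idx], df.loc[split.test_idx]
    m = train(ModelSpec("lr", seed=0, params={"C": 0.01}), tr, tr[["label_cmb"]],
              feature_names=preds)
    a = auroc(m.score_one(te), te["label_cmb"])
    assert 0.4 <= a <= 0.6


def test_experiment_grid_and_provenance(strong_dataset):
    res = run_experiment(
        1, strong_dataset, families=("lr",), tau_grid=((180.0, 60.0),),
        scenarios=("fv", "afv_onset", "afv_offset"), seed=0,
    )
    assert set(res["scenario"]) == {"fv", "afv_onset", "afv_offset"}
    assert (res["experiment"] == 1).all() and (res["scheme"] == "ss").all()
    summary = summarize(res)
    assert len(summary) == 3
    assert summary["mean_auroc"].between(0, 1).all()


def test_summarize_matches_hand_aggregation():
    rows = []
    for fold, a in enumerate([0.7, 0.8, 0.9]):
        rows.append({
            "experiment": 1, "scope": "pm", "scheme": "ss", "family": "lr",
            "tau_p": 180.0, "tau_f": 60.0, "scenario": "fv", "target": "label_cmb",
            "unit": "pm", "rep": 0, "fold": fold, "n_test": 10, "n_pos": 3,
            "auroc": a, "note": "",
        })
    s = summarize(pd.DataFrame(rows))
    assert s["mean_auroc"].iloc[0] == pytest.approx(0.8)
    assert s["median_auroc"].iloc[0] == pytest.approx(0.8)
    assert s["ci95_low"].iloc[0] < 0.8 < s["ci95_high"].iloc[0]


# --- intensity clustering -------------------------------------------------

def test_intensity_cluster_order_and_recovery(tiny_dataset):
    cl = intensity_clusters(tiny_dataset, seed=0)
    means = cl.groupby("cluster")["intensity_value"].mean()
    assert means.get("low", 0) <= means.get("mid", np.inf)
    if "high" in means.index and "mid" in means.index:
        assert means["mid"] <= means["high"]


def test_intensity_clusters_need_three_distinct_episodes():
    class Fake:
        def sessions(self):
            return iter(())

    with pytest.raises(ValueError):
        intensity_clusters(Fake())


# --- test-retest and correlations ----------------------------------------

def test_retest_grouping_arithmetic():
    df = pd.DataFrame({
        "participant": ["p"] * 7,
        "session_order": np.arange(7),
        "auroc": [0.8, 0.7, 0.9, 0.6, 0.65, 0.7, 0.5],
    })
    out = retest_by_session_group(df, group_size=3)
    assert list(out["sessions"]) == ["1-3", "4-6", "7-9"]
    assert out["complete"].tolist() == [True, True, False]
    for _, row in out.iterrows():
        members = df[df["session_order"] // 3 == row["group"]]["auroc"]
        assert members.min() <= row["median_auroc"] <= members.max()


def test_retest_stationary_has_no_trend():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({
        "participant": np.repeat([f"p{i}" for i in range(12)], 9),
        "session_order": np.tile(np.arange(9), 12),
        "auroc": 0.75 + 0.05 * rng.standard_normal(108),
    })
    out = retest_by_session_group(df)
    from scipy.stats import kendalltau

    tau = kendalltau(out["group"], out["median_auroc"])
    assert tau.pvalue > 0.05


def test_property_correlations_oracle():
    rng = np.random.default_rng(4)
    n = 20
    df = pd.DataFrame({
        "auroc": rng.uniform(0.5, 1.0, n),
        "n_sessions": rng.uniform(1, 10, n),
        "n_episodes": rng.uniform(0, 100, n),
        "mean_episode_duration_s": rng.uniform(1, 30, n),
        "total_duration_h": rng.uniform(1, 40, n),
    })
    out = property_correlations(df).set_index("property")
    # brute-force Spearman: Pearson on ranks (no ties by construction)
    for prop in out.index:
        rx = pd.Series(df[prop]).rank().to_numpy()
        ry = df["auroc"].rank().to_numpy()
        rho = np.corrcoef(rx, ry)[0, 1]
        assert out.loc[prop, "rho"] == pytest.approx(rho, abs=1e-12)


def test_property_correlations_flags_constant():
    df = pd.DataFrame({
        "auroc": [0.7] * 6,
        "n_sessions": np.arange(6, dtype=float),
        "n_episodes": np.arange(6, dtype=float),
        "mean_episode_duration_s": np.arange(6, dtype=float),
        "total_duration_h": np.arange(6, dtype=float),
    })
    out = property_correlations(df)
    assert (out["flag"] == "constant_input").all()


def test_property_correlations_perfect_monotone():
    df = pd.DataFrame({
        "auroc": np.linspace(0.5, 0.9, 8),
        "n_sessions": np.arange(8, dtype=float),
        "n_episodes": 8.0 - np.arange(8),
        "mean_episode_duration_s": np.arange(8, dtype=float) ** 2,
        "total_duration_h": np.arange(8, dtype=float),
    })
    out = property_correlations(df).set_index("property")
    assert out.loc["n_sessions", "rho"] == pytest.approx(1.0)
    assert out.loc["n_episodes", "rho"] == pytest.approx(-1.0)


# --- corpus statistics ----------------------------------------------------

def test_counts_summary_single_behavior_flagged():
    out = summarize_counts(10, 0, 0)
    assert out["pct_sib"] == 100.0
    assert np.isnan(out["ratio_sib_ed"]) and np.isnan(out["ratio_sib_ato"])


def test_corpus_summary_on_generated_dataset(tiny_dataset):
    out = corpus_summary(tiny_dataset)
    assert out["n_participants"] == 2 and out["n_sessions"] == 4
    assert out["total"] == sum(out["counts"].values())
    assert out["sessions_per_participant"]["median"] == 2.0
    assert out["session_duration_h"]["median"] == pytest.approx(0.25)


def test_corpus_summary_empty_dataset_rejected():
    class Empty:
        annotations = []
        manifest = pd.DataFrame(columns=["participant", "session", "bundle"])

        def sessions(self):
            return iter(())

    with pytest.raises(ValueError):
        corpus_summary(Empty())


def test_attrition_and_difference_conventions():
    assert attrition_pct(86, 16) == pytest.approx(18.6, abs=0.05)
    assert relative_difference_pct(0.72, 0.81) == pytest.approx(12.5, abs=0.05)
    with pytest.raises(ValueError):
        relative_difference_pct(0.0, 1.0)
    with pytest.raises(ValueError):
        attrition_pct(0, 0)
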