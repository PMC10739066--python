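"""Pseudolabeling domain adaptation: individualizing a population model.

A population model (PM) trained with the target participant held out scores
the target's unlabeled instances; confidently scored instances (probability
above ``p_hi`` or below ``p_lo``) become pseudolabeled training data, and
the model is refit on the pooled population data plus the weighted
pseudolabeled target data.  Iterating labels more target data as the model
individualizes.  Evaluation compares AUROC on a held-out labeled target
test set before vs after adaptation; the experiment-level output is the
median AUROC change across participants.

Target test labels are never visible to the adaptation loop: ``adapt``
receives unlabeled target training instances only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import auroc
from .models import FittedModel, ModelSpec, SingleClassError, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DAConfig:
    """Pseudolabeling hyperparameters.

    Instances scoring >= ``p_hi`` are pseudolabeled positive, <= ``p_lo``
    negative, the rest are left out of the refit.  The defaults (0.75 /
    0.25) reflect that class-balanced, strongly ridge-regularized
    probabilities rarely approach 0 or 1.  ``pseudo_weight`` is the share
    of the total training mass given to the pseudolabeled target set in
    the refit (0.5 = target and population weigh equally, regardless of
    their instance counts).  Iteration stops after ``max_iter`` rounds or
    when the coefficient vector moves less than ``tol`` (L2).
    """

    p_hi: float = 0.75
    p_lo: float = 0.25
    max_iter: int = 5
    pseudo_weight: float = 0.5
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lo < self.p_hi <= 1.0):
            raise ValueError("need 0 <= p_lo < p_hi <= 1")
        if not (0.0 < self.pseudo_weight < 1.0):
            raise ValueError("pseudo_weight is a mass share in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def pseudolabel(
    model: FittedModel, target_unlabeled: pd.DataFrame, cfg: DAConfig
) -> pd.DataFrame:
    """Confidently scored subset of the target instances with pseudolabels.

    Requires a probability-scoring model (LR/NN).  Returns a copy of the
    selected rows with ``pseudo_label`` and ``pseudo_weight`` columns;
    empty if nothing clears the thresholds.
    """
    scores = model.score_one(target_unlabeled)
    if np.nanmin(scores, initial=1.0) < 0 or np.nanmax(scores, initial=0.0) > 1:
        raise ValueError("pseudolabeling requires probability scores in [0, 1]")
    pos = scores >= cfg.p_hi
    neg = scores <= cfg.p_lo
    keep = pos | neg
    out = target_unlabeled.loc[keep].copy()
    out["pseudo_label"] = pos[keep].astype(int)
    out["pseudo_weight"] = cfg.pseudo_weight
    return out


@dataclass
class AdaptResult:
    participant: str
    pre_auroc: float
    post_auroc: float
    iterations: int
    n_pseudo_per_iter: list[int] = field(default_factory=list)
    flag: str = ""

    @property
    def delta(self) -> float:
        return self.post_auroc - self.pre_auroc


def adapt(
    pm_model: FittedModel,
    pm_train: pd.DataFrame,
    pm_train_label: str,
    target_unlabeled: pd.DataFrame,
    cfg: DAConfig,
) -> tuple[FittedModel, AdaptResult]:
    """Individualize ``pm_model`` to one participant via pseudolabeling.

    ``pm_train`` is the population training table (target excluded, LIO
    discipline); ``target_unlabeled`` is the target's adaptation split with
    labels withheld.  The refit pins the PM's selected ridge strength so
    iterations are comparable and deterministic.  If the first iteration
    yields no confident pseudolabels the PM is returned unchanged, flagged.
    """
    predictors = pm_model.feature_names
    chosen = pm_model.chosen_params.get(pm_train_label, {})
    spec = ModelSpec(
        family=pm_model.spec.family,
        seed=cfg.seed,
        params={**pm_model.spec.params, **chosen},
    )
    model = pm_model
    try:
        coef_prev = pm_model.coefficients(pm_train_label)
    except AttributeError:  # non-linear family: no coefficient stop rule
        coef_prev = None
    n_pseudo: list[int] = []
    iterations = 0
    for it in range(cfg.max_iter):
        pl = pseudolabel(model, target_unlabeled, cfg)
        n_pseudo.append(len(pl))
        if pl.empty:
            if it == 0:
                return pm_model, AdaptResult(
                    participant="", pre_auroc=np.nan, post_auroc=np.nan,
                    iterations=0, n_pseudo_per_iter=n_pseudo,
                    flag="no_confident_pseudolabels",
                )
            break
        X = pd.concat([pm_train[predictors], pl[predictors]], ignore_index=True)
        y = np.concatenate(
            [pm_train[pm_train_label].to_numpy(int), pl["pseudo_label"].to_numpy(int)]
        )
        # per-row weight giving the target set `pseudo_weight` of total mass
        row_w = (
            cfg.pseudo_weight / (1.0 - cfg.pseudo_weight) * len(pm_train) / len(pl)
        )
        w = np.concatenate([np.ones(len(pm_train)), np.full(len(pl), row_w)])
        try:
            model = train(spec, X, pd.DataFrame({pm_train_label: y}),
                          feature_names=predictors, sample_weight=w)
        except SingleClassError:
            break
        iterations = it + 1
        if coef_prev is not None:
            coef = model.coefficients(pm_train_label)
            if np.linalg.norm(coef - coef_prev) < cfg.tol:
                break
            coef_prev = coef
    return model, AdaptResult(
        participant="", pre_auroc=np.nan, post_auroc=np.nan,
        iterations=iterations, n_pseudo_per_iter=n_pseudo,
    )


def run_domain_adaptation(
    instances: pd.DataFrame,
    predictors: list[str],
    label: str = "label_cmb",
    cfg: DAConfig | None = None,
    family: str = "lr",
    train_frac: float = 0.8,
    purge_gap_s: float = 0.0,
) -> pd.DataFrame:
    """Experiment-8 driver over every participant of an instance table.

    For each target participant: the PM trains on all other participants;
    the target's sessions are split chronologically, the first
    ``train_frac`` (labels withheld) driving adaptation and the remainder,
    after a purge gap, serving as the labeled test set.  Returns one row
    per participant with pre/post AUROC, delta and bookkeeping.
    """
    cfg = cfg or DAConfig()
    rows = []
    for pid in sorted(instances["participant"].unique()):
        target = instances[instances["participant"] == pid]
        pop = instances[instances["participant"] != pid]
        tr_parts, te_parts = [], []
        for _, g in target.groupby("session"):
            t = g["t"].to_numpy()
            cutoff = t.min() + train_frac * (t.max() - t.min())
            tr_parts.append(g[t <= cutoff - purge_gap_s])
            te_parts.append(g[t > cutoff])
        tgt_train = pd.concat(tr_parts)
        tgt_test = pd.concat(te_parts)
        flag = ""
        try:
            pm = train(ModelSpec(family=family, seed=cfg.seed), pop, pop[[label]],
                       feature_names=predictors,
                       groups=(pop["participant"] + "/" + pop["session"]).to_numpy())
        except SingleClassError:
            rows.append({"participant": pid, "pre_auroc": np.nan,
                         "post_auroc": np.nan, "delta": np.nan,
                         "iterations": 0, "flag": "single_class_population"})
            continue
        pre = auroc(pm.score_one(tgt_test), tgt_test[label])
        adapted, res = adapt(
            pm, pop, label, tgt_train.drop(columns=[label]), cfg
        )
        post = auroc(adapted.score_one(tgt_test), tgt_test[label])
        if res.flag:
            flag = res.flag
            post = pre  # PM unchanged
        rows.append({
            "participant": pid,
            "pre_auroc": pre,
            "post_auroc": post,
            "delta": post - pre,
            "iterations": res.iterations,
            "n_pseudo": ";".join(map(str, res.n_pseudo_per_iter)),
            "flag": flag,
        })
    return pd.DataFrame(rows)


def delta_summary(report: pd.DataFrame) -> dict:
    """Median/IQR of per-participant AUROC deltas plus a one-sided sign test
    (positive deltas more likely than negative)."""
    d = report["delta"].dropna().to_numpy()
    n_pos, n_neg = int((d > 0).sum()), int((d < 0).sum())
    if n_pos + n_neg > 0:
        p = stats.binomtest(n_pos, n_pos + n_neg, alternative="greater").pvalue
    else:
        p = float("nan")
    return {
        "n": int(d.size),
        "median_delta": float(np.median(d)) if d.size else float("nan"),
        "iqr_low": float(np.percentile(d, 25)) if d.size else float("nan"),
        "iqr_high": float(np.percentile(d, 75)) if d.size else float("nan"),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "sign_test_p": float(p),
    }
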