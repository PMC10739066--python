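# aggrisk

Predicting **imminent aggressive behavior** — self-injurious behavior (SIB),
emotion dysregulation (ED), and aggression toward others (ATO) — in the next
1–3 minutes from the preceding 1–3 minutes of wrist-worn biosensor data
(Empatica E4 dialect: electrodermal activity at 4 Hz, blood volume pulse at
64 Hz, 3-axis acceleration at 32 Hz).

The package is aimed at researchers in affective computing and digital
psychiatry who want a fully reproducible, leakage-audited implementation of
the sliding-window prognostic workflow used in inpatient biosensing studies.
Because clinical recordings of this kind are not publicly deposited, it
ships a synthetic-data generator that emulates the corpus structure of such
a study (multi-participant, multi-session, self-exciting episode dynamics,
configurable pre-onset autonomic arousal), so every stage can be exercised
and validated end to end without any download.

## The model

At every decision time *t* (15-s cadence) a classifier estimates

> P( an episode onset occurs in (*t*, *t* + τ_f] | features of (*t* − τ_p, *t*] )

with τ_p, τ_f ∈ {60, 120, 180} s.  Feature vectors (FVs) hold the mean and
SD, across 15-s sub-windows, of eleven physiological base statistics
(EDA tonic level/slope, SCR count/amplitude; heart rate, SDNN, RMSSD from
BVP; acceleration magnitude mean/SD/max and jerk).  Augmented feature
vectors (AFVs) append two recency covariates: the count of recent episode
anchors and log1p(time since the last anchor), keyed to onsets or offsets.
Classifiers are ridge logistic regression (LR), RBF SVMs and small neural
networks behind one train/score contract; performance is AUROC under three
split schemes — chronological 80/20 session splits (SS, with a τ_p + τ_f
purge gap), leave-individuals-out (LIO) and leave-sessions-out (LSO)
5×5-fold CV — plus pseudolabeling domain adaptation for individualizing a
population model.  See `docs/methods.md` for the full account.

## Worked example

```python
from aggrisk.synthetic import scaled_preset, generate_sessions
from aggrisk.evaluation import run_experiment, summarize

# 6 participants x 2 sessions x 30 min, default arousal (15 bpm HR rise,
# 3x SCR-rate rise over the 180 s before each episode onset)
dataset = generate_sessions(scaled_preset(seed=0, n_participants=6,
                                          n_sessions=2, duration_s=1800.0))
results = run_experiment(
    1, dataset, families=("lr",), tau_grid=((180.0, 60.0),),
    scenarios=("fv", "afv_onset"), seed=0,
)
cols = ["family", "tau_p", "tau_f", "scenario", "mean_auroc", "n_folds"]
print(summarize(results)[cols].round(3).to_string(index=False))
```

prints

```
family  tau_p  tau_f  scenario  mean_auroc  n_folds
    lr  180.0   60.0 afv_onset       0.909        1
    lr  180.0   60.0        fv       0.911        1
```

i.e. on this small strong-signal corpus, a population LR evaluated on the
held-out last 20% of each session separates pre-onset from background
windows with AUROC ≈ 0.91; recency augmentation neither helps nor hurts
here because the corpus is small and the physiological ramp already carries
the signal (its benefit appears on self-exciting, weaker-signal corpora).

The same pipeline is scriptable from the shell:

```bash
aggrisk simulate --preset desk --seed 1 --out data/desk
aggrisk run --data data/desk --experiments 1,3 --models lr \
    --tau-p 180 --tau-f 60 --seed 1 --out results/run1
aggrisk report --results results/run1 --data data/desk
aggrisk adapt --data data/desk --seed 1 --out results/da
```

Each command writes a JSON run manifest capturing configuration, seed and
versions, so runs are bit-reproducible.

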