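# imufatigue

Similarity-weighted personalization for detecting biceps-muscle fatigue from
wrist IMU recordings of dumbbell concentration curls.

The pipeline: 6-channel 50 Hz accelerometer/gyroscope sets are segmented into
repetitions (trough-to-trough on the gyroscope x-axis), labeled fatigue /
non-fatigue from Borg RPE reports reconciled against heart rate (fatigue iff
effective RPE > 16), enriched with three derived channels (total
acceleration, exerted force, complementary-filter yaw), and summarized by
eleven features per repetition on each of nine channels. A test subject is
compared against a crowd through min–max-normalized Manhattan distances over
physical traits (age, height, weight, BMI) and over the per-repetition
feature block of one exercise set; exponential similarities
`exp(-gamma * d)` are blended with weights alpha + beta = 1, and the blended
score weights each crowd subject's rows when training boosted decision-tree
or neural-net classifiers. Evaluation drivers cover leave-one-subject-out
cross-validation, gamma and alpha/beta sweeps, test-subject data-budget
curves with accuracy-gain ratios, and cross-subject vs personalized vs
subject-specific comparisons.

A seeded synthetic cohort generator (`imufatigue.synthetic`) produces
25-subject cohorts with the structure the method assumes — movement-style
clusters correlated with physical traits, RPE trajectories crossing the
fatigue threshold in late sets, and planted fatigue signatures (slower
cycles, amplitude change, positive skew) — so every stage is exercisable
without any data download.

## CLI

Everything is reachable through one entry point:

```sh
imufatigue simulate --seed 1 --out cohort/ --subjects 25 --coupling 1.0
imufatigue segment cohort/ --out segmentation.csv
imufatigue features cohort/ --out features.csv
imufatigue rank cohort/ s01 --gamma 14 --out ranking.csv
imufatigue train cohort/ --subject s01 --mode personalized --out model.joblib
imufatigue predict model.joblib features.csv --out predictions.csv
imufatigue sweep-gamma cohort/ --grid 0,2,4,8,14 --out gamma_sweep.csv
imufatigue sweep-ab cohort/ --step 0.05 --out alpha_sweep.csv
imufatigue budget cohort/ --out budget.csv
imufatigue compare cohort/ --out comparison.csv
```

Defaults (sampling rate, segmentation knobs, alpha/beta/gamma, model
hyper-parameters, budget basis) live in `imufatigue.config.DEFAULTS` and can
be overridden with `--config my.yaml` plus per-command flags. Every run
writes a `<subcommand>_manifest.txt` next to its outputs.

Cohorts on disk are plain CSV: one directory per subject holding
`traits.csv`, `sets.csv`, and one `<hand>_set<k>.csv` signal file per set
(`timestamp,ax,ay,az,gx,gy,gz`; set 0 is the warm-up).

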