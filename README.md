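# fescom

Hybrid filter–wrapper feature selection for recognising upper-limb
rehabilitation exercises from wearable inertial sensors.

Home-based rehabilitation programs ask patients to repeat prescribed
upper-limb exercises; a wrist-worn inertial measurement unit (IMU) records
tri-axial acceleration (g) and angular velocity (°/s), and a classifier
decides which exercise each repetition was. With 10 statistical features per
channel the feature vector is 60-dimensional, and many of those features are
irrelevant or redundant for the recognition task. This package implements
**FESCOM**, a two-stage hybrid feature-selection method, together with the
full surrounding pipeline: recording I/O, median-filter preprocessing,
time/frequency feature extraction, an evaluation harness, and a synthetic
IMU data generator so every stage is testable end to end.

## The method

**Filter stage.** For feature *k* and every unordered pair of motion classes
(*i*, *j*), a two-sample Welch *t* test on the per-class feature values gives
a two-sided P value *P*<sub>*k*</sub>(*i*, *j*). With *C* classes there are
*C*(*C*−1)/2 pairs; the *significance index* of feature *k* is

  *s*<sub>*k*</sub> = mean(*P*<sub>*k*</sub>) + sd(*P*<sub>*k*</sub>)

A small mean says the feature separates class pairs on average; a small SD
says it does so uniformly, so smaller *s* means stronger discriminative
capacity. Features with *s* below a threshold (default 0.05) form the
*candidate set*, ranked ascending.

**Wrapper stage.** Sequential forward selection (SFS) over the candidate
set: starting from the empty subset, each step evaluates the stratified
5-fold cross-validated error rate of the current subset extended by each
remaining candidate, keeps the best extension, and stops when no extension
strictly reduces the error. The wrapping component is pluggable: 1-nearest
neighbour (Euclidean), Gaussian naive Bayes, or a 20-tree random forest.
Search cost is accounted as the number of classifier fits, a
hardware-independent proxy for search time; pruning the feature pool in the
filter stage is what makes the hybrid cheaper than wrapping all 60 features.

**Features** (per channel, 10 types): mean, standard deviation, maximum,
minimum, kurtosis, skewness, interquartile range; average power (mean square),
average frequency and median frequency of the one-sided periodogram with the
DC bin excluded.

## Worked example

```python
import fescom

# simulate the five-exercise protocol: 21 subjects x 5 exercises x 3 reps
spec = fescom.default_protocol_spec(seed=7)
windows, _ = fescom.generate_dataset(spec)
table = fescom.build_feature_table(windows)
print(f"{table.n_samples} windows x {table.n_features} features")

records = fescom.rank_features(table)
print(fescom.significance_report(records).head(5).to_string(index=False))

train, test = fescom.split(table, train_fraction=0.7, seed=7)
clf = fescom.ClassifierSpec("knn", {"k": 1})
candidates, trace = fescom.fescom_select(train, clf, threshold=0.05, folds=5, seed=7)
err = fescom.holdout_error(train, test, trace.selected, clf)
print(f"candidates: {len(candidates)} of 60; selected: "
      f"{[train.names[i] for i in trace.selected]}")
print(f"train CV error {trace.final_error:.3f}, held-out error {err:.3f}, "
      f"{trace.fit_count} classifier fits")
```

prints

```
315 windows x 60 features
                     feature_name       mean_p         sd_p            s  rank
    avg_frequency(acceleration_x) 2.892663e-41 9.147109e-41 1.203977e-40     1
    avg_frequency(acceleration_y) 9.584131e-41 3.030278e-40 3.988692e-40     2
    avg_frequency(acceleration_z) 4.927746e-40 1.557836e-39 2.050611e-39     3
avg_frequency(angular_velocity_x) 7.671005e-39 2.423499e-38 3.190600e-38     4
             mean(acceleration_z) 1.358265e-32 3.654877e-32 5.013142e-32     5
candidates: 34 of 60; selected: ['avg_frequency(acceleration_y)', 'avg_power(acceleration_z)']
train CV error 0.000, held-out error 0.011, 335 classifier fits
```

The top-ranked features sit on the four informative channels the simulator
plants (the spectral features pick up the class-distinct movement
frequencies); the filter admits 34 of 60 features at the 0.05 threshold, and
the wrapper then needs only two of them to reach ~1% held-out error while
fitting far fewer models than a search over all 60 features would.

## Command-line interface

```bash
fescom synthgen --seed 7 -o data/            # simulate recordings + annotations
fescom extract data/subject_00.csv data/subject_00_annotations.csv -o features.csv
fescom rank features.csv -o significance.csv # Table-style significance report
fescom select features.csv --classifier knn --threshold 0.05 --seed 7 -o selection.json
fescom compare --seed 7 -o report/           # hybrid vs plain wrapper, CSV + JSON
fescom curve features.csv --classifier knn -o curve.csv  # error vs feature count
```

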