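# hemiconn

Hemispheric asymmetry analysis of multimodal resting-state brain data:
EEG functional connectomes, fMRI functional connectomes, and EEG band power,
compared across modalities subject by subject.

## Who this is for

Network-neuroscience researchers asking whether the left–right asymmetry of a
subject's functional connectome covaries with the asymmetry of their
electrophysiological band power — for example across clinical subgroups
(inattention / motion / mixed ADHD profiles).  Raw-data preprocessing
(fMRIPrep, FreeSurfer, ICA) is out of scope: the pipeline starts from
channel-level EEG time series and parcel-averaged fMRI time series.

## The core statistic

For a hemispheric quantity *X* with *N* nodes per hemisphere, the asymmetry
index is

```
AI(X) = 100 · (|X(R)| − |X(L)|) / N        AI ∈ [−100, +100]
```

positive AI = rightward dominance, negative = leftward.  Three metrics feed
this formula:

* **FC-fMRI** — an 84-parcel (42 per hemisphere) Pearson-correlation
  connectome; each node's *contralateral degree of centrality* is the sum of
  its correlations with all nodes of the opposite hemisphere.  *X* uses the
  per-node mean contralateral correlation so that AI respects its ±100 range;
  area-level AI restricts the source nodes to one of five lobar areas
  (frontal, central, temporal, parietal, occipital).
* **FC-EEG** — the same construction on a 30-channel (15 per hemisphere)
  broadband "time-EEG" connectome.
* **power-EEG** — relative multitaper band power (delta [1,4), theta [4,8),
  alpha [8,13), beta [13,30) Hz) averaged over the 3 channels of each
  (hemisphere, area) group.

Across subjects, the fMRI and EEG asymmetries are compared per (area, band)
cell by Pearson correlation and by one-component PLS regression (permutation
p for R²); group differences use one-way ANOVA with Tukey HSD; all asymmetry
statistics are validated against degree-preserving randomized-network nulls
(Maslov-style weight rewiring).

Because there is no public raw cohort bundled here, a synthetic generator
produces band-structured EEG (narrowband oscillations + 1/f noise + ocular
artifact) and factor-structured fMRI signals in which a single subject-level
latent couples the two modalities' asymmetries at a chosen correlation —
so every stage is testable against known ground truth.

## Worked example

```sh
cat > demo.yaml <<'EOF'
n_perm: 999
simulation:
  n_subjects: 19
  eeg_duration: 20.0
  fmri_volumes: 120
  cross_modal_r: 0.6
EOF
hemiconn full --config demo.yaml --seed 7 --out demo_ws
hemiconn report --config demo.yaml --seed 7 --out demo_ws
```

The `full` run simulates a 19-subject inattention-profile cohort whose
latent asymmetry couples fMRI connectivity and alpha-band power at r = 0.6,
then computes band power, connectomes, asymmetry profiles and cohort
statistics.  `report` prints:

```
strongest cross-modal correlation cells (by p):
  inattention  FC-fMRI~powerEEG   alpha  frontal    r=+0.589 p=0.0080 PLS R2=0.347
  inattention  FC-fMRI~powerEEG   beta   frontal    r=-0.583 p=0.0088 PLS R2=0.340
  inattention  FC-fMRI~powerEEG   delta  frontal    r=-0.545 p=0.0158 PLS R2=0.297
  inattention  FC-fMRI~powerEEG   theta  frontal    r=-0.541 p=0.0168 PLS R2=0.292
  ...
```

The injected alpha coupling is recovered (r = +0.59 at n = 19), and the
other bands anticorrelate: relative power is a zero-sum budget per channel,
so a rightward alpha shift depresses the remaining bands on the right —
the same mixed-sign pattern across bands that motivates this analysis in
real cohorts.  Result CSVs (`asymmetry.csv`, `stats_correlations.csv`, …)
carry provenance headers (`# hemiconn=…, config_hash, seed`) and are
byte-identical across reruns with the same config and seed.

The randomized-network control is available as
`hemiconn nulls --config demo.yaml --seed 7 --out demo_ws`, which writes
null AI distributions and null cross-modal correlations with empirical
p-values.

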