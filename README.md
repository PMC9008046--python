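# eegraph

Resting-state EEG functional-connectivity analysis for comparing mild
cognitive impairment (MCI) subtypes — for clinical-neurophysiology and
network-neuroscience researchers who want the whole chain, from epoched
multichannel EEG to group-level inference and classifier benchmarking, as a
tested and reproducible library.

The pipeline:

1. **Coherence connectivity.** For each pair of channels *x*, *y*, the
   magnitude-squared coherence

   COH<sub>xy</sub>(f) = |S<sub>xy</sub>(f)|² / ( S<sub>xx</sub>(f) · S<sub>yy</sub>(f) )

   is estimated from the epoch-averaged cross-spectral density
   S<sub>xy</sub>(f) (one Hann-tapered FFT segment per 2-s epoch) and
   averaged over the bins of each frequency band — delta (0.1–4 Hz), theta
   (4–8 Hz), alpha (8–13 Hz), beta (13–30 Hz), gamma (30–50 Hz) — giving one
   weighted adjacency matrix W ∈ [0, 1]<sup>19×19</sup> per band per subject
   (19 channels of the international 10–20 montage).
2. **Graph measures.** Twelve global measures of the weighted undirected
   network: average degree and strength, radius, diameter, characteristic
   path length, global and local efficiency, clustering coefficient,
   transitivity, modularity (Louvain), assortativity and small-worldness.
   Path-based measures use connection lengths L = 1/W.
3. **Group statistics.** Two-sided permutation tests (5000 relabelings by
   default, exact enumeration for tiny groups) on every measure × band,
   Benjamini–Hochberg FDR across the family, and Pearson correlations
   between selected measures and cognitive test scores.
4. **Classification.** Six standard classifiers (logistic regression,
   linear SVM, random forest, gradient boosting, a small neural network,
   Gaussian naive Bayes) on selected graph measures plus sex and MMSE,
   evaluated with stratified 70/30 splits repeated 10 times; precision,
   recall, accuracy, F1 and ROC AUC from test-fold confusion counts.
5. **Synthetic cohorts.** Because clinical EEG cohorts of this kind are not
   publicly deposited, the package ships a generator that emulates the data
   shape exactly (subjects × 10 epochs × 19 channels × 400 samples at
   200 Hz) with controllable band-specific module structure, group effects
   and covariates — every downstream stage is testable against known ground
   truth.

## Worked example

Generate a 30-per-group cohort in which group B's beta-band intra-module
coupling is raised by 0.15, run the full pipeline, and benchmark the
classifiers on the two discriminative measures plus sex and MMSE:

```python
import eegraph as eg

cohort = eg.SyntheticCohortConfig(n_per_group=30, group_effect={"beta": 0.15}, seed=7)
pipe = eg.PipelineConfig(n_permutations=2000, louvain_restarts=5,
                         sw_nulls=5, sw_rewires_per_edge=2)

subjects, covariates = eg.generate_cohort(cohort)
graphs = [(s.subject_id, eg.subject_connectivity(s, pipe.bands)) for s in subjects]
metrics = eg.metrics_table(graphs, pipe, seed=0)

stats = eg.compare_groups(metrics, covariates, pipe, seed=0)
print(stats[stats.significant][["measure", "band", "mean_A", "mean_B",
                                "p_perm", "p_fdr"]].round(4).to_string(index=False))

fm = eg.build_features(metrics, covariates,
                       ["modularity_beta", "radius_gamma", "sex", "mmse"])
print(eg.reports_to_frame(eg.evaluate_classifiers(fm, pipe, seed=0))
      [["classifier", "precision", "recall", "accuracy", "f1", "auc"]]
      .round(3).to_string(index=False))
```

Output:

```
               measure band  mean_A  mean_B  p_perm  p_fdr
              strength beta  4.4846  4.9174  0.0005 0.0043
                radius beta  8.4429  8.9222  0.0075 0.0500
     global_efficiency beta  0.2523  0.2766  0.0005 0.0043
      local_efficiency beta  0.2058  0.2131  0.0045 0.0337
clustering_coefficient beta  0.3350  0.3019  0.0005 0.0043
          transitivity beta  0.3350  0.3019  0.0005 0.0043
            modularity beta  0.3207  0.3696  0.0005 0.0043
         assortativity beta  0.3976  0.4941  0.0005 0.0043
       small_worldness beta  0.5179  0.4218  0.0005 0.0043
         classifier  precision  recall  accuracy    f1   auc
logistic_regression      0.814   0.778     0.800 0.795 0.899
                svm      0.840   0.756     0.806 0.795 0.895
      random_forest      0.795   0.778     0.789 0.787 0.870
  gradient_boosting      0.772   0.789     0.778 0.780 0.854
     neural_network      0.812   0.767     0.794 0.789 0.847
        naive_bayes      0.777   0.811     0.789 0.793 0.885
```

Every significant difference lands in the beta band — the band that carries
the planted effect — and group B's modularity is higher (0.37 vs 0.32), as
expected when within-module coupling is raised. The classifiers separate
the groups well above chance (AUC ≈ 0.85–0.90) from four features.

A command-line interface mirrors the library:

```bash
eegraph synth-cohort --config cohort.yaml --out-dir data/
eegraph connectivity --epochs data/A000.csv --epochs data/B030.csv --out graphs.csv
eegraph graph-metrics --graphs graphs.csv --out metrics.csv
eegraph group-stats --metrics metrics.csv --covariates data/covariates.csv --out stats.csv
eegraph classify --metrics metrics.csv --covariates data/covariates.csv \
    --features modularity_beta,radius_gamma,sex,mmse --out report.csv
```

EDF recordings are read with `eegraph.read_edf` (channels canonicalised to
the 19-label montage, continuous records segmented into 2-s epochs).

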