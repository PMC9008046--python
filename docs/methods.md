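# Methods

## Data model

A subject is an `EpochSet`: a tensor of `n_epochs × n_channels × n_samples`
in µV with channel labels from the 19-electrode 10–20 montage (Fp1, Fp2,
F7, F3, Fz, F4, F8, T3, C3, Cz, C4, T4, T5, P3, Pz, P4, T6, O1, O2) and a
sampling rate. The reference geometry throughout is ten 2-s epochs at
200 Hz (400 samples per epoch). EDF files are read through mne with
physical dimensions converted to µV; continuous records are segmented into
non-overlapping consecutive 2-s windows, dropping any trailing partial
window. Clinical practice selects non-consecutive artefact-free epochs by
expert review; that selection is upstream of this package and cannot be
reproduced from data alone, so consecutive segmentation is the documented
deterministic default. Channel order is always canonicalised to the montage
list so adjacency matrices are comparable across subjects and files. The
reference montage of the recording is not modelled: signals are analysed
as-is, and coherence values are referencing-dependent.

## Coherence estimation

Each epoch is mean-detrended, Hann-tapered and Fourier-transformed as a
single Welch segment; cross-products are averaged over epochs to give the
cross-spectral density `S_xy(f)` on a 0.5 Hz grid (for the reference
geometry). Magnitude-squared coherence per bin is
`|S_xy|² / (S_xx S_yy)` ∈ [0, 1]; the band value is the mean over bins in
the half-open interval `[f_low, f_high)`, DC always excluded, so the delta
band's nominal 0.1 Hz edge effectively starts at 0.5 Hz. Epochs are not
sub-segmented: ten epochs supply the estimator's degrees of freedom, and
splitting 2-s windows would destroy delta-band resolution. Coherence from
one segment is identically 1 and is rejected (`DegenerateEstimatorError`),
as is a channel with zero in-band power (`DegeneratePowerError` rather than
silent NaN propagation).

Two estimation conventions exist in the field: band-averaging the full
coherence spectrum (used here) versus time-domain bandpass filtering before
coherence. Band-averaging avoids filter-edge artefacts and needs only one
spectral decomposition; the alternative is noted, not implemented.

With K independent epochs the estimator's independence bias is ≈ 1/K
(about 0.10 at K = 10); the calibration tests measure this against an
independent scipy-based Monte-Carlo baseline rather than assuming the
analytic value.

## Graph measures

Networks are dense weighted undirected graphs (no thresholding by default,
which avoids arbitrary sparsification; an optional `edge_threshold`
configuration is recorded in output metadata when used). Conventions, all
standard for connectivity-weighted brain networks:

* **Connection lengths** for path-based measures are `L = 1/W`: stronger
  coherence = functionally closer. All path-based measures inherit this
  choice, so it is worth stating prominently.
* **Degree / strength**: counts of positive-weight edges and sums of
  incident weights, averaged over nodes.
* **Radius / diameter / characteristic path length / global efficiency**:
  from all-pairs shortest paths (vectorised Floyd–Warshall — validated
  against an independent Dijkstra oracle). Eccentricities are taken over
  finite distances; disconnected pairs are excluded from the CPL mean and
  contribute zero to efficiency, keeping all measures finite.
* **Clustering / transitivity**: Onnela geometric-mean triangle intensity
  `(ŵ_ij ŵ_ih ŵ_jh)^{1/3}` with weights rescaled by the maximum weight;
  per-node normalisation `k_i (k_i − 1)`, isolated and degree-1 nodes
  contribute 0.
* **Local efficiency**: the weighted per-node form
  `Σ_{j≠h∈N_i} (w_ij w_ih / d_jh(N_i))^{1/3} / (k_i (k_i − 1))`, with
  `d_jh(N_i)` the shortest path restricted to the neighbour subgraph.
* **Modularity**: weighted Newman modularity with resolution γ (default 1),
  maximised by Louvain with randomised node-order restarts (default 10;
  best Q kept). On ≤ 12 nodes an exhaustive set-partition search
  (`exhaustive_modularity`) provides the exact optimum used to audit the
  heuristic; at 19 nodes, 10 restarts are stable in practice.
* **Assortativity**: weighted Pearson correlation of endpoint strengths
  across edges (each edge weighted by its weight, both orientations).
  Degenerate variance — e.g. a regular ring, where all strengths are
  equal — is defined as 0 with a warning.
* **Small-worldness**: σ = (C/⟨C₀⟩)/(L/⟨L₀⟩) against degree-preserving
  surrogates (default 20 surrogates, 10 rewiring attempts per edge).
  The surrogate generator performs Maslov–Sneppen edge swaps with weights
  travelling on their edges. On a *complete* graph — and band-averaged
  coherence graphs are complete — no swap can succeed, which would make the
  surrogate identical to the original and σ ≡ 1 for every subject. The
  surrogate therefore additionally permutes the weight values uniformly
  across the (rewired) edge set, preserving every node's degree and the
  weight multiset while giving a non-degenerate null on dense graphs
  (`permute_weights=False` restores the pure-swap null).

Exact self-checks: radius ≤ diameter always holds and is tested; the bound
"global efficiency ≥ 1/CPL" is *not* generally true for weighted graphs
and is not asserted. Clustering, transitivity and modularity are invariant
to uniform weight scaling; distances scale as 1/k under W → kW — each
tested. The stochastic measures (Louvain restarts, small-world surrogates)
are reproducible under a fixed seed; `metrics_table` derives one rng stream
per subject × band from the master seed so results do not depend on
processing order.

## Group statistics

Each measure × band is compared between the two groups with a two-sided
permutation test on the difference of group means,
`p = (1 + #{|null| ≥ |observed|}) / (n_perm + 1)` (5000 permutations by
default; random relabelings are sampled without enforcing uniqueness).
When `C(n_A + n_B, n_A) ≤ 10 000` the test switches to exhaustive
enumeration and p is exact. The statistic and sidedness are documented
defaults — common practice when a "non-parametric permutation test" is
specified without further detail. The FDR family is all measure × band
tests of one comparison (12 × 5 = 60) adjusted by Benjamini–Hochberg; the
family is configurable since the choice (per band, per measure, or both)
is a genuine analysis decision. Correlations between selected measures and
cognitive scores are plain Pearson r with unadjusted two-sided p, matching
the screening usage of post-hoc score correlations. A Welch-t demographics
summary is provided as reporting convenience only.

## Classification

Features are selected graph measures (named `measure_band`) plus covariate
columns, typically sex and MMSE. Standardisation is fit on each training
fold inside the split loop — leakage-free is the defensible default when
the original protocol is unspecified. All six classifiers see the identical
stratified 70/30 splits (10 repeats under the master seed): logistic
regression, linear-kernel SVM, 100-tree random forest, gradient boosting
(library default depth), a one-hidden-layer perceptron (lbfgs, width
max(4, 2 × features) — a width-2 ReLU layer can initialise entirely dead on
1–2-feature problems and collapse to a constant), and Gaussian naive Bayes.
Hyperparameters are fixed, not tuned: reproducibility over benchmark
chasing. Confusion counts are pooled over repeats (micro-average) for the
four reported metrics; per-repeat values including AUC are also emitted
because the aggregation convention (pooled vs averaged) is itself a choice.
AUC uses predicted probabilities where available, otherwise decision
scores.

## Synthetic cohort generator

The generator is the package's stand-in for a clinical cohort; its defaults
*are* the study conditions under which the validation experiments run.

Per band b, each channel mixes a module-shared and a global latent
oscillator:

    x_c(t) = Σ_b [ α_b · s_{m(c),b}(t) + β_b · s_{g,b}(t) ] + ε_c(t)

where the latents are unit-variance white noise band-limited to b by FFT
masking (pure sinusoids would concentrate power in single bins and make
coherence estimation degenerate), and ε is white sensor noise. Defaults:
intra-module coupling α = 0.6 and inter-module coupling β = 0.3 in every
band, noise SD 1 µV, per-subject per-band jitter of SD 0.05 on α, three
scalp-region modules (frontal / central-temporal / posterior — a labelling
convenience; no volume conduction or leadfield mixing is modelled). These
values put within-module band coherence around 0.5 and between-module
coherence around 0.1 at the reference geometry: strong but not saturated
module structure, so modularity estimates have realistic subject-level
variance.

A group effect is an additive per-band shift of group B's intra-module
coupling; the package's reference planted effect is +0.15 in the beta band
(`REFERENCE_GROUP_EFFECT`), chosen during design as an effect a 60-per-group
study detects with high power (observed standardised difference in beta
modularity ≈ 1 at the defaults). Covariates mimic the shape of an
MCI-subtype table: per-group female probability (0.71 vs 0.47), per-group
MMSE mean/SD (26 ± 3 vs 24 ± 3.8), and cognitive z-scores that load
linearly on the subject's true coupling deviation (score =
λ · deviation/jitter-SD + unit noise), so Pearson-correlation recovery has
a known sign and approximate magnitude. Each subject's rng stream is
derived from the master seed and the subject counter, making cohorts
bit-reproducible and independent of generation order.

What the generator deliberately does **not** emulate: 1/f background
spectra, volume conduction and common-reference leakage, artefacts
(blinks, drowsiness), non-stationarity across epochs, and realistic
clinical effect sizes (none are published for this design). Passing tests
therefore demonstrate the *machinery* — estimator calibration, measure
correctness, error control, power under a known effect — not clinical
validity on real EEG.

## Validation experiments and their scales

The heavyweight experiments (also recomputed by `scripts/acceptance.py`)
use reduced stochastic-measure settings — Louvain restarts 3, 2 small-world
surrogates with 1 rewiring pass — and 500 permutations for the type-I
study; these settings affect per-subject measure noise identically in both
groups, and the type-I property holds for any exchangeable statistic.
Scales: 200 null cohorts of 20 subjects/group for the type-I calibration
(the fraction of raw p < 0.05 is compared against the discrete-grid nominal
level 25/501 using the empirical across-cohort standard error — the 60
tests within a cohort are correlated, so a plain binomial bound over all
12 000 tests would be anti-conservative); 20 cohorts of 60 subjects/group
at the reference effect for the power study (2000 permutations, so the
smallest attainable p of 1/2001 remains FDR-significant at rank 1 of 60);
100 random graphs with n ≤ 8 for measure-oracle agreement at 1e−9; 20
random 8-node graphs for the Louvain audit.

## Known limitations

* Coherence is sensitive to volume conduction and the recording reference;
  robust alternatives (imaginary coherency, wPLI) are out of scope.
* Dense 19-node coherence graphs make average degree trivially 18; any
  sparsification that produces lower reported degrees in clinical studies
  is analysis-specific and not reverse-engineered here (the
  `edge_threshold` option exists, default off, and the choice is recorded
  in output metadata).
* Exact weighted-measure variants differ across toolboxes; the variants
  implemented (Onnela clustering, strength assortativity, inverse-weight
  lengths) are named in `GraphMetricsRecord.metadata`.
* Permutation tests compare means without covariate adjustment;
  age/education-adjusted comparisons are out of scope.
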