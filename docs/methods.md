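# Methods

This note documents the models, statistics and design choices behind
`mea-addict`, including where the procedure was genuinely open and what
the synthetic data do and do not establish.

## Recording model and spike detection

A *session* is one 15-minute acquisition of a multiwell plate at one step
of a cumulative dosing ladder (vehicle step, then five rising doses, with
a standing time between recordings).  Each well carries 16 extracellular
electrodes.  The optional raw-voltage path mirrors a standard MEA
acquisition chain at 12.5 kHz:

- **High-pass filter**: 4th-order Butterworth at 200 Hz, applied
  forward–backward (zero phase) so detected spike times do not shift with
  the filter setting.  The filter family is a package choice; only the
  cutoff is prescribed by the assay.
- **Noise floor**: σ is estimated as 1.4826 × the median absolute
  deviation of the samples in the quietest 50% of 1-s windows (ranked by
  mean power).  "Quiescent period" has no standard definition; the
  MAD/low-power rule is robust to residual spikes by construction and is
  validated in tests (σ recovered within 5% on clean noise, 10% with
  spikes inserted).
- **Spike detection**: two-sided threshold at ±5.3σ; one event per
  suprathreshold excursion, timed at the sample of largest |amplitude|;
  events closer than a 1-ms refractory window merge.  The refractory
  default is a package choice.

## Network-burst detection (four-step)

Spikes of all electrodes are pooled into 100-ms bins.  The four steps:

1. count spikes per bin;
2. flag bins with count ≥ `rate_threshold`;
3. merge flagged runs separated by ≤ `merge_gap_ms` (default 200 ms);
4. discard candidates with < `min_spikes_per_nb` spikes (default 10) or
   spikes on fewer than `min_electrodes` electrodes (default 25% of the
   well's active electrodes).

Burst start/end snap to bin edges, then refine to the first/last member
spike.  All four thresholds are configuration, not constants.

`rate_threshold` defaults to a **fixed 5 spikes/bin**.  An adaptive rule
(max of 5 and 25% of the 99th-percentile bin count) is available as
`rate_threshold="adaptive"` but is not the default: for bursts with a
roughly triangular intensity envelope, a flagging level proportional to
the peak rate systematically truncates the rising and falling flanks —
at 25% of peak, about a quarter of every burst's true duration is lost,
biasing Duration, IBI and Duration IQR.  With the fixed level the
truncation is bounded by `5/peak_bin_count` (a few percent for healthy
cultures) and the spike-count and electrode guards suppress chance
background bins (at 0.6–0.8 background spikes per pooled bin, a bin
reaching 5 spikes is rare and never carries the 10 spikes needed to pass
step 4).

### The 13 analytical parameters

Per recording of a well: TS (total spikes, all electrodes), number of
NBs, IBI (mean end-to-next-start gap), Duration (mean), Spikes per NB
(mean), MF (mean over NBs of the largest 100-ms bin count inside each
NB), IMFI (mean gap between successive NB peak-bin times), the four
coefficients of variation CV(Duration), CV(Spikes), CV(MF), CV(IMFI)
(sample SD / mean), Periodicity, and Duration IQR
(linear-interpolation quartiles).

**Missing-value policy.**  TS and the NB count are always defined.  With
one NB the per-burst means exist but every interval/dispersion parameter
is missing (NaN, never zero).  CV(IMFI) needs at least two intervals.  A
zero-mean CV divisor makes the CV missing with a warning.  Downstream, a
(compound, concentration, phase) group enters PCA only through its rows
complete on the subset under evaluation; groups with fewer than 3
complete wells are excluded.  This policy exists because real cultures
can stop bursting at high doses (the simulator's ethanol analogue
reproduces exactly that).

**Periodicity.**  No standard formula exists for a bounded "periodicity
of network activity" score, so the package defines one: the normalized
autocorrelation of the mean-subtracted 100-ms histogram; the score is
the height of the largest local maximum at lag ≥ 3 bins, clipped to
[0, 1].  A perfect burst comb scores ≈ 1, a homogeneous Poisson train
scores < 0.2 with high probability, constants score 0.

### Vehicle normalization

Each well's vehicle-step recording within a session defines 100%; dose
values become `100 × value / vehicle_value` per parameter, per well, per
phase.  A zero or missing vehicle value produces a missing normalized
value (never ±∞), logged.  Normalizing per session cancels per-well
baselines and the maturation drift between the two sessions, so what
remains is each well's *dose responsiveness* — which is exactly what the
chronic comparison asks about.

## Statistics

- **One-way ANOVA + Dunnett** (dose–response heat maps): classic
  equal-variance two-sided Dunnett against the vehicle group; adjusted
  p-values come from the multivariate-t distribution of the simultaneous
  t statistics (via `scipy.stats.dunnett`, seeded for determinism).  A
  single comparison reduces exactly to the pooled-variance t-test.
  Monte-Carlo cross-checks and a familywise-error calibration
  (0.05 ± 0.01 over 5000 null replicates) are part of the test suite.
- **Two-group multivariate test** (phase shifts on PC scores): Hotelling
  T² with its exact F transform; Wilks' Λ = 1/(1 + T²/(n₁+n₂−2)) is
  reported as well — for two groups they are the same test.  A singular
  pooled covariance receives a tiny trace-scaled ridge (10⁻⁸) with a
  warning.
- α = 0.05 throughout.  No multiplicity correction is applied across the
  8178 subsets; the search is explicitly exploratory and in-sample, and
  its stability is assessed by simulation instead (below).

## Subset search

The matrix for a subset holds one row per well × concentration × phase
(dose rows only — baseline rows are identically 100 after normalization
and carry no information).  Columns are z-scored with the sample SD;
PCA is the eigendecomposition of the resulting correlation matrix;
components are ordered by variance and sign-fixed (largest-|loading|
entry positive) so projections are reproducible.  Standardization is
necessary because the 13 parameters have incommensurate units.

**Qualification.**  Per compound, the before- vs after-chronic clouds
are compared on PC1/PC2.  The dose rows of one well share that well's
vehicle-step divisor, so they are correlated; treating them as
independent replicates would overstate the evidence (pseudoreplication).
The test therefore uses **per-well mean scores** — one observation per
well per phase, wells being the genuinely independent units (n = 10 per
phase in the default design).  A subset qualifies when every
addictive-profile compound shifts at p < 0.05 while no non-addictive
compound (vehicle included) does.  A compound that cannot be tested
(missing phase, < 3 wells) disqualifies the subset.

**Selection.**  Among qualifying subsets the winner minimizes the mean
log p of the per-concentration before/after tests across the addictive
compounds (25 independent 10-vs-10 tests in the default design).  With a
strong planted effect, many subsets reach extreme significance and any
single small test ranks them mostly by the tail noise of its estimated
2×2 covariance; averaging 25 log p values makes the ranking stable —
in repeated planted-effect simulations the selected subset contains all
four planted burst-timing parameters in 50/50 replicates, versus ~86%
when ranking by the single pooled test's worst p.  Qualification and
selection therefore use the same contrast at two granularities.
Ties (exact score equality) break toward smaller subsets, then
lexicographically.  The search is fully deterministic.

## Classification

Wells are projected with the selected model; centroids are arithmetic
means per compound × concentration × phase (≥ 3 wells); the chronic
shift of a group is the Euclidean PC1–PC2 distance between its two phase
centroids.  The decision threshold is **2 × the sample SD of the
vehicle's own before/after shift distances**, by default the *per-well*
shift distances pooled over the vehicle's concentrations (50 values in
the default design).  The per-concentration centroid variant
(`threshold_mode="per_concentration"`) is available but not the default:
with the threshold and the tested quantity both on the centroid scale,
2 × SD sits at ≈ 1.3 × the Rayleigh scale of *any* null compound's
centroid distance, which would flag every null compound with probability
≈ 0.3–0.4 per concentration.  Per-well distances put the threshold on
the single-well noise scale — about √n_wells above centroid noise — so
genuine chronic shifts must clear a solvent-calibrated margin while null
centroids fall far below it.

A compound is called addiction-like when at least one concentration
exceeds the threshold; the call is reported as "≥ lowest positive
concentration", and non-monotone positivity patterns are reported
verbatim with a flag.

**Known limitation.**  The threshold is calibrated on the vehicle alone.
Normalized values are ratios, so their absolute noise scales with their
mean: a compound whose acute response parks a parameter far from 100%
carries proportionally more noise than the vehicle, and its null
distances are underestimated by a vehicle-only threshold.  The procedure
is therefore reliable when acute responses stay within roughly the
solvent's own range on the selected parameters, and conservative
interpretation is warranted for strong acute responders.  (Log-scale
standardization would remove this heteroscedasticity but would change
the published procedure, so it is not done here.)

## Synthetic study generator

The simulator generates what the analysis assumes, not a biophysical
neuron model:

- Per electrode, homogeneous Poisson background firing
  (default 0.4 Hz/electrode, 16 electrodes).
- Network bursts from a Gamma renewal process (mean interval 12 s,
  shape 8 → interval CV ≈ 0.35, giving visible but imperfect
  periodicity).  Each burst is an inhomogeneous Poisson packet with a
  triangular intensity envelope, LogNormal duration (median 0.5 s,
  log-SD 0.25), peak pooled rate 80 spikes per 100-ms bin, shared across
  a random 85% subset of electrodes.  Expected recoverable values of
  n_NB, Duration, Spikes, MF, IBI and IMFI follow in closed form
  (`BurstProcessParams.expected_parameters`) and the analysis recovers
  them within 10% — generator and analyzer are independent code paths.
- **Acute effects** are multiplicative Hill curves on the process
  parameters, identical in both phases.  Directions follow the known
  acute pharmacology of the reference compounds (e.g. the
  nicotine-analogue raises firing, the varenicline-analogue lowers
  firing while raising burst counts).  Magnitudes are the package's
  choice: they are kept within roughly ±15–20% at the top dose for the
  non-addictive profiles — clearly detectable in the Dunnett
  dose–response analysis, while respecting the homoscedasticity envelope
  of the vehicle-calibrated threshold discussed above.  The vehicle
  itself (DMSO analogue) has mild dose effects on firing and burst
  timing, reflecting that solvents measurably perturb cultured networks
  — the 2SD threshold exists precisely to absorb that solvent-scale
  variation.
- **Chronic shifts** are multiplicative changes applied in the
  after-chronic phase to *dose* recordings only, modelling chronically
  altered responsiveness to compound challenge; a uniform baseline change
  would be removed by the per-session vehicle normalization in any case.
  Addictive profiles shift burst timing — interval ×0.65–1.6,
  duration median ×0.68–1.4, duration log-SD ×1.25–1.3 — which
  propagates into IBI, Duration, IMFI and Duration IQR (and, through the
  interval, into burst counts, as chronic effects do in practice).
  Non-addictive and vehicle profiles have chronic shift ≡ 1, enforced by
  the profile validator.  The ethanol analogue additionally stops
  bursting entirely at its top dose after chronic exposure, exercising
  the missing-value path end to end.
- **Noise**: per-well LogNormal baseline multipliers (CV 15%) shared
  across all of a well's recordings, plus smaller per-recording state
  fluctuations (CV 6%).  All randomness derives from the study seed via
  documented `numpy` seed-list substreams
  (`[seed, 1, compound, well]` for baselines,
  `[seed, 2, compound, well, phase, dose]` per recording), so identical
  designs and seeds reproduce identical plates, features and calls.

A feature-level generator (`planted_feature_table`) plants a
multiplicative chronic effect (default ×1.5, well noise CV 12%) directly
in chosen columns of a normalized table; it is the fast harness used to
calibrate subset-search recovery with many replicates, where the
spike-level path would add nothing but runtime.

**What passing tests show — and do not.**  The synthetic study verifies
the pipeline's statistical machinery: burst detection against a
brute-force reference, analytic round trips, test calibration, planted
signal recovery, and end-to-end sensitivity/specificity under the
generator's assumptions (multiplicative effects, LogNormal noise,
renewal bursts).  Real cultures have structure the generator omits —
non-stationarity within a session, electrode-level heterogeneity and
dropout, desensitization under cumulative dosing, plate edge effects —
so passing here demonstrates correctness of the method, not performance
on any particular biological preparation.

## Default study design

Ten compound profiles (five addictive analogues: nicotine, ethanol,
flunitrazepam, phenobarbital, methamphetamine; four non-addictive:
varenicline, muscimol, amantadine, acetaminophen; DMSO vehicle), ten
wells per compound (at least eight required), five cumulative doses plus
a vehicle step per session, 900-s recordings, both phases: 12 sessions
and 1200 well recordings per study.  Dose ladders follow the screening
ranges of the corresponding reference compounds (ethanol and DMSO dosed
in %, others in μM).  A full simulated study runs in ≈ 15 s and the
8178-subset search in ≈ 2 s on one CPU, so the acceptance experiments
(50 replicated searches, 5000-replicate test calibrations) complete in a
few minutes.
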