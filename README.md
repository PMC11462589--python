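# mea-addict

Screening pipeline for **addiction-like responses** in multiwell
microelectrode-array (MEA) recordings of cultured neuronal networks —
e.g. human iPSC-derived dopaminergic neurons exposed to candidate
compounds before and after a period of chronic administration.

The question the pipeline answers: *given 15-minute spike recordings of
each well at a vehicle step plus five cumulative doses, taken once before
and once after chronic exposure, which compounds changed the network's
dose responsiveness in the way addictive reference compounds do?*

## Method

1. **Network-burst analysis.** Spikes of all electrodes in a well are
   pooled into 100-ms bins and array-wide network bursts (NBs) are
   detected with a four-step rule (flag bins above a spike-count
   threshold, merge flagged runs across short gaps, discard candidates
   with too few spikes or electrodes, refine edges to member spikes).
   Each recording is summarised by 13 analytical parameters: total spikes
   (TS), number of NBs, inter-burst interval (IBI), NB duration, spikes
   per NB, max frequency (MF — the largest 100-ms bin count per NB,
   averaged), inter-MF interval (IMFI), the coefficients of variation of
   duration/spikes/MF/IMFI, a periodicity score, and the interquartile
   range of NB durations.
2. **Vehicle normalization.** Every parameter is expressed per well as a
   percentage of that well's own vehicle-step recording in the same
   session (vehicle = 100%), removing per-well baselines and maturation
   drift between sessions.
3. **Exhaustive parameter-subset search.** All 8178 subsets of ≥ 2 of the
   13 parameters are evaluated.  Per subset, a standardized PCA is fitted
   to the well-level normalized rows and each compound's before- vs
   after-chronic score clouds are compared on PC1/PC2 (two-group
   Wilks/Hotelling test on per-well mean scores).  A subset *qualifies*
   when all addictive reference compounds shift significantly
   (p < 0.05) and no non-addictive compound does; the most significant
   qualifying subset is selected.
4. **2SD classification.** Wells are projected with the selected model;
   for every compound × concentration the Euclidean distance between the
   before- and after-chronic centroids on the PC1–PC2 plane is compared
   against a threshold of twice the SD of the vehicle's (DMSO) own
   before/after shift distances.  Distances above the threshold are
   addiction-like responses.

Dose–response statistics (one-way ANOVA with Dunnett's many-to-one
comparison against vehicle) are provided for the per-parameter heat-map
view.

Because raw recordings of such studies are rarely public, the package
ships a seeded synthetic plate simulator (`mea_addict.simulate`):
Poisson background firing plus Gamma-renewal network bursts with
triangular intensity envelopes, Hill-type acute dose effects, and
chronic shifts of burst timing for addictive-profile compounds only.

## Worked example

```python
import mea_addict as ma

design = ma.default_design(seed=42)       # 10 compounds x 10 wells, 2 phases
result = ma.run_study(design)             # simulate -> features -> search -> classify

sel = result.selection
print("+".join(sel.best.subset), sel.n_qualifying)
print(result.classification.threshold)
print(result.classification.compound_calls[
    ["compound", "label", "addiction_like", "lowest_positive"]
])
```

prints (seed 42):

```
n_NB+Duration 2082
0.7027...
       compound         label  addiction_like lowest_positive
           DMSO       vehicle           False            none
  acetaminophen non_addictive           False            none
     amantadine non_addictive           False            none
        ethanol     addictive            True       >= 0.03 %
  flunitrazepam     addictive            True       >= 0.1 uM
methamphetamine     addictive            True       >= 0.3 uM
       muscimol non_addictive           False            none
       nicotine     addictive            True         >= 1 uM
  phenobarbital     addictive            True         >= 1 uM
    varenicline non_addictive           False            none
```

2082 of the 8178 parameter subsets satisfy the addictive-only shift
criterion at this seed; the most significant one (burst count + burst
duration) is used for classification.  The distance threshold 0.70 is
2 × the SD of DMSO's own per-well before/after shift distances on the
PC plane.  All five addictive-profile compounds exceed it from their
lowest tested concentration upward; none of the non-addictive profiles
does.  The ethanol analogue loses bursting entirely at its top dose
after chronic exposure, so that concentration is reported from the four
analysable doses.

The same workflow is available from the shell:

```bash
mea-addict simulate --seed 42 --out plates/
mea-addict features --plates plates/ --out features.csv
mea-addict search --features features.csv --report report.csv --model model.json
mea-addict classify --features features.csv --model model.json --out results/
```

## Layout

| module | contents |
| --- | --- |
| `mea_addict.recording` | spike-list CSV + YAML sidecar I/O, vendor-CSV compat reader, high-pass filter, noise-σ estimate, ±5.3σ spike detection |
| `mea_addict.bursts` | four-step NB detector, 13 parameters, feature tables, vehicle normalization, Dunnett dose-response summary |
| `mea_addict.stats` | one-way ANOVA, Dunnett many-to-one, two-group Wilks/Hotelling test |
| `mea_addict.search` | subset enumeration, standardized PCA, qualification search, model selection |
| `mea_addict.classify` | projection, centroid shift distances, 2SD vehicle threshold, compound calls |
| `mea_addict.simulate` | burst-process simulator, compound profiles, study designs, planted-effect tables |
| `mea_addict.pipeline` | `run_study` / `analyze_plates` orchestration |
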