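# m6adose

Radiation biodosimetry from RNA N6-methyladenosine (m⁶A) biomarkers.

After a radiological accident, the absorbed dose of ionizing radiation must
be reconstructed from biology, because physical dosimeters are rarely worn.
The m⁶A modification level of specific transcripts (*Ncoa4*-like persistent
markers, *Ate1*/*Fgf22*-like early markers) in peripheral blood mononuclear
cells rises with dose in a saturating, time-dependent way and stays
measurable for weeks. `m6adose` implements the complete analysis chain for
this kind of study, for epitranscriptomics and radiation-biology groups:

1. **Array quantification** (`m6adose.epiarray`) — two-channel (IP/Sup)
   probe intensities are spike-in normalized per channel (each log₂
   intensity shifted by the negative mean log₂ spike-in intensity), then

   level(%) = 100 · IP / (IP + Sup),  quantity = normalized IP.

   Differential methylation between exposed and control groups is called by
   fold change (> 2 or < 0.5, strict) and a two-sided t-test on log₂ levels
   (p < 0.01).
2. **Two-stage biomarker screen** (`m6adose.screening`) — transcripts are
   categorized per timepoint (Hyper / Hypo / Inconsistent), the Hyper
   category is sub-clustered by fuzzy c-means on z-standardized temporal
   log₂FC profiles (`m6adose.cluster.FuzzyCMeans`, a scikit-learn
   estimator), the consistently hyper-methylated sub-cluster is selected by
   the sign of its raw mean profile, and candidates are the intersection
   with independent single-timepoint hyper sets from a lower-dose exposure.
3. **qPCR arithmetic** (`m6adose.qpcr`) — MeRIP-qPCR IP enrichment
   E = eff^(Ct_input − Ct_IP) · m_input/m_IP (amounts rescaled to equal RNA
   mass), ΔΔCt relative expression, SELECT single-base m⁶A fractions via a
   linear standard curve of relative product r = 2^(Ct − Ct_100%) against
   fraction, and one-way ANOVA with a Monte-Carlo Dunnett many-to-one
   adjustment.
4. **Dose reconstruction** (`m6adose.dosimetry`) — inverse-regression
   calibration: per-timepoint quadratic dose = b₀ + b₁m + b₂m², and an
   integrated bivariate cubic over all 10 monomials mⁱtʲ (i+j ≤ 3) in
   (m⁶A level, time post irradiation). Both are scikit-learn estimators
   (`QuadraticDoseModel`, `BivariateCubicDoseModel`). Performance is
   R² on training data plus rank-based ROC AUC at dose cutoffs under
   100× repeated stratified five-fold cross-validation.
5. **Synthetic studies** (`m6adose.synthetic`) — every input the pipeline
   consumes can be simulated with known ground truth: a Hill-in-dose ×
   log-normal-in-time response surface, planted hyper/hypo transcripts over
   a null transcriptome, spike-in probes around sample scale factors, and
   Ct values generated by inverting the quantification formulas.

## Worked example

Run the whole pipeline on the default simulated study (gamma-ray doses
0, 0.2, 0.5, 1, 2, 4, 6.5 Gy; days 1–28; n = 5 per group):

```bash
m6adose run-all --outdir demo --seed 0
```

which prints

```
m6adose 0.1.0 pipeline run (seed 0)

screen: 30 consistent-hyper genes (stage I), 20 candidates after intersection
merip: ANOVA F = 146.071, p = 8.40862e-20
select: standard curve r2 = 0.997364
fit-dose: integrated model R2 = 0.818981 (per-TPI quadratic R2 0.766038-0.945628)
evaluate: cv mean AUC 0.2 Gy -> 0.863592, 0.5 Gy -> 0.92088, 1 Gy -> 0.958627, 2 Gy -> 0.992611, 4 Gy -> 0.992765, 6.5 Gy -> 0.932483
```

Reading the output: the stage-I screen finds 30 consistently
hyper-methylated transcripts, and intersecting with the independent 2 Gy
exposure prunes these to exactly the 20 planted persistent biomarkers
(the 10 transient ones drop out). The MeRIP enrichment differs strongly
across dose groups (ANOVA F = 146). The integrated (m⁶A, time) → dose model
explains 82% of dose variance across all timepoints, and classification of
"dose ≥ cutoff" from model-predicted doses is excellent at intermediate
cutoffs, with the 0.2 Gy cutoff hardest — there only the sham group sits
below the cutoff, and a 0.2 Gy exposure barely moves m⁶A above baseline.
Every table and model is written under `demo/` together with
`manifest.json` (seed, full configuration, config hash): rerunning with the
same manifest reproduces every output byte for byte.

Each stage is also available as its own subcommand (`simulate`,
`quantify-array`, `screen`, `merip`, `select-curve`, `fit-dose`,
`evaluate`) over plain TSV/JSON files, and as plain library calls.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its limits, numerical choices, and known limitations.
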