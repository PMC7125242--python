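# strainrepro

Reproducibility and sample-size planning for paired-observer myocardial
strain measurements from cardiovascular magnetic resonance feature tracking
(CMR-FT).

## The problem

When a new imaging biomarker such as global myocardial strain is brought
into animal research, two questions decide whether it is usable: *how well
do two observers (or one observer on two occasions) agree*, and *how many
animals does a future study need* to detect a given change, given that
observer variability. `strainrepro` implements the full analysis chain for
a two-observer, two-replicate porcine study design across three inotropic
states — baseline (BL), dobutamine hypercontractility (Dob) and verapamil
hypocontractility (Ver):

1. **Aggregation** — segmental strain readings on the 16-segment AHA model
   (6 basal, 6 mid, 4 apical; the apical cap is excluded) are averaged,
   replicates first, then segments, into global longitudinal (GLS),
   circumferential (GCS) and radial (GRS) strain, in percent.
2. **Agreement** — Bland–Altman analysis of paired differences *d = a − b*
   (bias `mean(d)`, SD with the n−1 denominator, 95% limits of agreement
   `bias ± 1.96·SD`) and the intraclass correlation coefficient from
   two-way ANOVA mean squares (default variant: absolute agreement, single
   measures, ICC(A,1), with F-based 95% CIs). ICCs are classified as
   excellent (> 0.74), good (0.60–0.74), fair (0.40–0.59) or poor (< 0.40).
3. **Sample size** — the number of animals needed to detect a change of
   δ strain points given the SD σ of between-measurement differences:

   n = round( 2 · f(α, P) · σ² / δ² ),   f = 10.5 for α = 0.05, power = 0.80,

   with a floor of one animal and dropout inflation `ceil(n / (1 − rate))`.
4. **Synthetic data** — a seeded generator emulating the study design
   (10 animals × 3 states × 3 components × 16 segments × 2 observers × 2
   replicates), with per-cell population means and between-animal SDs,
   additive observer bias and analysis-session noise, so the whole chain is
   testable without any measured data.

## Worked example

Desk calculation — animals needed per detectable GLS change, with the
design's pooled difference SD of 4.9 strain points:

```sh
$ strainrepro samplesize --sigma 4.9 --delta 5 --delta 10 --delta 15 --dropout 0.25
component,sigma,sigma_source,delta,f,alpha,power,required_n,dropout_rate,inflated_n
strain,4.9,explicit,5.0,10.5,0.05,0.8,20,0.25,27
strain,4.9,explicit,10.0,10.5,0.05,0.8,5,0.25,7
strain,4.9,explicit,15.0,10.5,0.05,0.8,2,0.25,3
# delta=5: required 20 animals, 27 after 25% dropout
# delta=10: required 5 animals, 7 after 25% dropout
# delta=15: required 2 animals, 3 after 25% dropout
```

Twenty animals detect a 5-point GLS change with 80% power at α = 0.05;
five suffice for a 10-point change; planning for 25% dropout raises those
to 27 and 7.

Full synthetic pipeline (generate → aggregate → agreement → sample size):

```sh
$ strainrepro run-all --seed 42 --out out/
{"outputs": ["global_strain.csv", "agreement.csv", "bland_altman_points.csv",
 "sample_size.csv", "sample_size_curve.csv"], "seed": 42}
```

`agreement.csv` then holds 18 rows (2 comparisons × 3 components × 3
states); e.g. the baseline inter-observer GLS row of a seed-42 run
(rounded to two decimals):

```
comparison,component,state,n,mean_diff,sd_diff,loa_lower,loa_upper,icc,icc_ci_lower,icc_ci_upper,category
inter_observer,longitudinal,BL,10,-0.52,1.88,-4.21,3.17,0.94,0.78,0.98,excellent
```

i.e. observer 2 reads GLS about half a strain point higher than observer 1,
95% of paired differences fall within roughly ±3.7 points of the bias, and
agreement is excellent. Re-running with the same seed reproduces every
artifact byte for byte (`manifest.json` records seed, config hash and
outputs).

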