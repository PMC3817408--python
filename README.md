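# promscale

Global versus specific transcriptional regulation, quantified from
fluorescent-reporter growth curves.

When a microbial culture is moved between growth conditions, the activity
of nearly every promoter changes — yet most of that change is not specific
regulation.  For most promoters the activity in condition *B* is the
activity in condition *A* times a single constant, the **global scaling
factor** *S*[*A,B*], which depends on the conditions but not on the
promoter.  In a scatter of activities between two conditions those
promoters fall on a ray through the origin (the *scale line*); the
promoters that deviate from it by more than three experimental standard
deviations are the genuinely condition-specific response.  `promscale`
implements this decomposition end to end for plate-reader reporter assays
(OD plus YFP/GFP time series, with an optional constitutive RFP channel):

* **activity extraction** — promoter activity as the reporter production
  rate per OD unit per second,
  `P = (F(t2) − F(t1)) / ∫ OD dt`, inside a window of two OD doublings at
  maximal growth (yeast mode) or a 3-h mid-exponential window (ecoli
  mode), with background subtraction, Hampel outlier smoothing, a
  detection level from promoter-less control wells, and replicate
  averaging;
* **error model** — the activity-dependent replicate CV (large for barely
  detectable promoters, ~0.05 for strong ones), binned and interpolated;
* **scale lines** — robust origin-anchored fits (Tukey bisquare IRLS) per
  condition pair, variance explained by projection onto the ray,
  permutation p-values, and two global/specific classifiers (3-SD rule;
  ±30% rule above an activity floor);
* **proportional clustering** — spherical k-means under the cosine metric
  `d(x,y) = 1 − cos∠(x,y)` (invariant to rescaling a profile, so clusters
  are groups that preserve internal ratios), with K chosen as the largest
  K keeping all centers ≥ 0.05 apart, per-cluster scaling-factor tables
  and a re-clustering stability check;
* **prediction** — activities in an unmeasured condition from ~10
  representative promoters via extended cluster centers (or a best-linear-
  sum predictor for greedily selected representatives), with
  leave-one-condition-out evaluation;
* **factor models** — two parameter-free predictions of *S*[*A,B*]: the
  growth-rate model `S = τA/τB` and the passive resource-allocation model
  `S = (τA/τB)·(f_glo[B]/f_glo[A])`, which treats total promoter activity
  per doubling time as a conserved resource partitioned between the
  global and specific responses;
* **enrichment** — hypergeometric tests of promoter sets against flat
  annotation tables with Benjamini–Hochberg correction;
* **synthetic data** — a plate-reader simulator with planted cluster
  structure, self-consistent global factors, logistic growth and an
  activity-dependent noise model, so the whole pipeline is testable
  without any external data.

## Worked example

```sh
promscale demo --seed 0 --out demo_out
```

simulates 500 promoters × 6 conditions (3 replicates each, plus control
and blank wells), runs every stage, writes the tables into `demo_out/`,
and prints:

```
recovered vs planted global factors:
           recovered   planted
ethanol     0.270329  0.267937
galactose   0.352375  0.351801
glucose     1.000000  1.000000
glycerol    0.328682  0.326383
heat        0.422642  0.424470
osmotic     0.274927  0.276190
selected K = 6, clustering variance explained = 0.9997
                 r2  k  n_promoters  n_representatives  frac_within_3cv
condition
ethanol    0.996087  6          500                 10            0.994
...
```

Reading this: the robust pairwise fits recover every planted global
scaling factor within ~1%; the cosine k-means selects exactly the six
planted proportional groups, whose rays account for 99.97% of the pooled
variance of the 500 × 6 activity matrix; and with only 10 representative
promoters measured in a held-out condition, the activities of all other
promoters are predicted with r² ≥ 0.996, with ≥ 98.6% of promoters within
three experimental standard deviations of their measured value.

The same stages are available on files (`promscale simulate / activity /
errmodel / scale / cluster / predict / models / enrich`) and as library
functions (`promscale.pairwise_scaling`, `promscale.fit_clusters`, …).

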