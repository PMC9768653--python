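# cogbattery

Analysis pipeline for cognitive test batteries in wild animal populations,
built around the study design used for cooperative breeders such as the
southern pied babbler (*Turdoides bicolor*): individuals are tested on a
battery of learning tasks (associative learning, reversal learning,
inhibitory control), each scored as **trials to criterion** — the number
of trials taken to produce six correct choices in a row, capped and
censored at 120 trials (lower = better).

The package answers the three questions such studies ask:

1. **Is there a general cognitive factor?**  Scores are correlated across
   tasks (Spearman), and an unrotated PCA of the correlation matrix
   extracts **GCP (general cognitive performance)** — the sign-flipped
   first principal component, so higher GCP means fewer trials.  Because
   a PCA always produces a first component, its credibility is checked
   against a within-task permutation null: scores are shuffled among
   individuals within each task 10 000 times, and the observed mean and
   s.d. of the PC1 loadings are compared with the null 95% intervals.
   Repeatability of GCP across replicate batteries is estimated as an
   intraclass correlation, `R = σ²_between / (σ²_between + σ²_within)`,
   with a parametric-bootstrap CI and a permutation p-value.

2. **What drives individual variation in GCP?**  Candidate linear mixed
   models (group identity as a random intercept; age, sex, rank, group
   size, motivation proxies, study year, testing order as candidate
   terms, plus pairwise additive and interaction models) are ranked by
   AICc, `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`.  The *top model set*
   contains models within 2 ΔAICc of the best whose interpreted fixed
   coefficients have 95% CIs excluding zero.

3. **Does GCP predict fitness?**  Yearly reproduction measures for
   dominant breeders (fledglings, offspring surviving to independence,
   recruits) are modelled with Poisson mixed models with crossed year
   and individual random intercepts (Laplace-approximated maximum
   likelihood), ranked the same way.

A noncentral-F power module (`Cohen's f²`) sizes the smallest detectable
fixed effect, and a synthetic-data generator produces rosters,
trial-level batteries and multi-year breeding histories with known
ground truth so every stage can be validated by parameter recovery.

## Worked example

Simulate a 38-bird study and run the whole pipeline:

```bash
cogbattery simulate --seed 7 --outdir sim
cogbattery run --trials sim/trials.csv --roster sim/roster.csv \
    --breeding sim/breeding.csv --outdir out --n-sims 10000 --seed 7
```

which prints (abridged):

```
scored 38 individuals; per-task summary:
              mean  min  max  n_censored   n
associative  35.11    6  120           2  38
reversal     57.39   10  120           8  38
inhibitory   37.39    6  102           0  38
PC1 explains 57.46% of score variance; mean loading 0.75
  (null 95% CI 0.01-0.68; above CI: True)
fitness (fledglings, n=240): top model set ['gcp']
```

Reading this output: the three tasks average 35–57 trials to criterion
with a handful of censored (120-trial) birds; the first principal
component carries 57% of the score variance and its mean loading (0.75)
exceeds the permutation-null upper bound (0.68), so the shared axis is
not a PCA artefact; and in the breeding analysis the GCP model is the
only member of the top model set for yearly fledglings, with coefficient
−0.24 ± 0.09 (95% CI −0.42; −0.06) on the log link — individuals with
higher cognitive performance fledged *fewer* young per year, the
cognition–reproduction trade-off this design is built to detect (the
generator's true effect here is −0.18 per s.d. of GCP).

Every stage is also callable as a library function
(`cogbattery.extract_gcp`, `cogbattery.permutation_null`,
`cogbattery.fit_mixed`, `cogbattery.run_fitness_models`, ...) or as a
CLI subcommand (`simulate | score | criterion | gcp | repeatability |
select | fitness | power | run`).

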