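# Methods

`satay_fitness` estimates the fitness effect of gene disruptions from a
single SATAY (SAturated Transposon Analysis in Yeast) dataset: a pooled
library of transposon insertion mutants, grown competitively for ~10
generations and sequenced once, yielding one read count per unique
insertion site. This note describes the model, the choices behind every
tunable constant, what the built-in simulator does and does not emulate,
and the numerical conventions that make results reproducible.

## Growth model and fitness scales

Each insertion mutant is assumed to start from a single cell and grow
Malthusianly, `N(t) = 2^(mu*t)`, so its final read count is a noisy proxy
for `2^(mu*t)`. All sites mapped to one gene are treated as replicate
measurements of the same disruption; their mean read count `y_hat_g` is
the Poisson maximum-likelihood estimate of the gene's read level. Fitness
is normalised to the population median on the premise that most gene
disruptions are near-neutral, on two scales:

* **median scale** `w_g = log2(y_hat_g) / median[log2(y_hat_g)]` — time
  drops out of the ratio; genes whose mean read count falls below 1
  (an excess of imputed zero-read sites) get `w < 0`, which should be
  read as "frequently lost through the sampling bottleneck", not as an
  elevated death rate;
* **generation scale** `w_g = (y_hat_g / median[y_hat_g])^(1/t)` with
  `t = 10` generations of library expansion — the per-generation
  frequency-ratio scale used by competition assays, with mutant and
  reference starting frequencies set to 1 (at most one transposon per
  site at induction).

The two scales normalise by the median of the logs and the log of the
median respectively; these differ slightly when the gap between the
middle genes is wide. Both are implemented exactly as defined rather than
reconciled. The median scale is invariant to the log base (a ratio of
same-base logs); tests assert this.

## Per-gene read set

The read sample of a gene is assembled in a fixed order:

1. **Assignment and edge exclusion.** Sites with `start <= pos <= end`
   belong to the gene. The relative position along the coding strand is
   `(pos - start)/L` on `+` genes and `(end - pos)/L` on `-` genes;
   sites with relative position outside `[0.10, 0.90)` are excluded from
   the read sample, because insertions in the outer 10% of a coding
   region — especially near the stop codon, where the transposon only
   truncates the protein — often fail to knock the gene out. The
   half-open convention fixes the boundary behaviour exactly.
2. **Zero-site imputation.** Mutants lost in the sampling steps leave no
   reads; ignoring them floors `y_hat` at 1 and erases the low-fitness
   tail. The number of lost sites is estimated as
   `max(0, E(X_g) - O(X_g))`, with `E(X_g) = floor(lambda(r_cg) * L_g)`
   from the bias model below and `O(X_g)` the observed insertion count
   over the **full** gene (edge sites included — the same denominator as
   `E`, which uses the full gene length; counting only central sites is a
   config switch, `impute_full_gene = False`). The imputed sites enter
   the sample as read count 0 and carry no position.
3. **Outlier trimming.** Reads above `q95 + 1.5*(q95 - q5)` of the
   gene's read distribution (zeros included) are removed. Percentiles use
   linear interpolation between order statistics (the default convention
   of the standard stats routines), which fixes the threshold exactly.
   The rule is upper-tail only: zeros are structural evidence of lost
   mutants and are never trimmed.
4. **Status.** A gene with fewer than 5 sites after trimming, or with
   only zeros left, is reported `undetermined` and excluded from
   normalisation and comparisons.

## Centromere-bias model

The MiniDS transposon reinserts preferentially near its excision site
beside the centromere, elevating insertion density within roughly 200 kb
of each centromere (between about 0.12 bp^-1 near the centromere and
0.067 bp^-1 distally in published libraries). The correction:

* accumulate, per chromosome arm, the number of insertions within
  distance `r_c` of the centromere (grid step 1 kb by default; sites
  inside the centromere interval get distance 0; the average at `r` is
  taken over arms whose observed extent reaches `r`, so short arms never
  truncate the tail);
* fit a cubic to the arm-averaged cumulative curve over 0–400 kb,
  unweighted (shorter curves are fitted on the available range with a
  warning);
* the insertion rate `lambda(r_c)` is the **derivative** of that cubic
  for `r_c < 200 kb` and is held constant at `lambda(200 kb)` beyond —
  the far tail of a polynomial derivative oscillates and is not trusted.
  `lambda` is continuous at the cutoff by construction; a fit whose rate
  dips below zero anywhere on the fit range is rejected with an error.

Gene distance `r_cg` is measured from the gene center
(`floor((start+end)/2)`) to the nearer centromere edge. `E(X_g)` is
rounded down to an integer because insertion counts are discrete.

Numerics: the cubic is solved by least squares on a rescaled abscissa
(`r / 100 kb`) and the coefficients converted back to bp units; the
normal equations in raw bp are numerically singular (`r^3 ~ 1e17`).

## Overdispersion and uncertainty

Read counts of one gene are modelled as negative binomial,
`Var(Y) = mu + alpha*mu^2`; `alpha = 0` is the Poisson limit. A single
`alpha` is shared genome-wide (all counts are conditional on the same
sequencing depth), estimated as the no-intercept OLS slope (statsmodels)
of `(s2_g - y_hat_g)/y_hat_g` on `y_hat_g` over genes with at least two
retained sites and positive mean; a negative slope clamps to 0 with a
warning, and fewer than 10 usable genes is an error. Sample variances use
the `n-1` denominator and include imputed zeros (switchable); trimmed
reads are excluded, matching the pipeline order. The per-gene variance is
`V_g = max(y_hat_g + alpha*y_hat_g^2, s2_g)` — the trend never
underestimates a gene's own spread — and `SE_g = sqrt(V_g / n)` with `n`
the number of sites used for the gene's mean. The SE is stated on the
read-count scale, deliberately not propagated through the log/median
scaling.

## Diagnostics, replicate comparison, saturation

* **Bin profiles** split each coding region into 20 coding-strand
  segments and report reads per insertion per segment, pooled over a gene
  class (weighting every insertion equally; a per-gene-mean variant is
  available). Edge insertions are included here on purpose — the
  diagnostic must show the effect the fitness pipeline excludes. Bins
  without insertions are undefined (NaN), not zero.
* **Insertion-free span**: the largest gap between consecutive insertions
  within a gene (gene boundaries as sentinels), as a fraction of gene
  length; 1.0 for insertion-free genes. Long spans are the classic
  essentiality signal; essentiality *calling* is out of scope.
* **Replicate comparison** matches insertion sites of two libraries
  one-to-one within a 2-bp window (read mapping is only that accurate).
  Candidate pairs are taken greedily in a symmetric order — lower
  coordinate, then distance, then the partner coordinate — so the result
  is invariant under swapping the datasets. An unmatched site counts
  toward the differential-presence tally `delta_P` only if it has >= 2
  reads. Read differences `delta_R` at matched sites are reported raw and
  depth-normalised (reads per total mapped); the normalised absolute
  difference is the headline. Per-gene fitness tables are compared over
  genes determined in both datasets with `E(X) >= 5` in both.
* **Saturation** emulates a sequencing run of depth `n` as an exact
  multivariate hypergeometric draw (one urn colour per site) from the
  pooled reads, then reruns the whole pipeline per depth, reporting
  unique insertions, reads per site, and the distribution of relative
  standard errors. The default depth grid is 10 log-spaced points from 1%
  to 100% of the total.

## The simulator

`synthetic_data` forward-simulates the exact generative process the
estimators assume, so every estimator has a recovery test with known
truth. Stages: per-bp Bernoulli insertion placement with the biased rate;
clonal expansion `2^(mu*t)`; a multinomial harvest bottleneck; per-site
gamma amplification factors (mean 1, variance `alpha`) absorbing PCR
noise; Poisson read sampling. The gamma-Poisson compound gives exactly
the negative-binomial mean-variance law the dispersion model fits. PCR is
not simulated cycle-by-cycle; its net effect is the NB dispersion.
Replicate pairs can be split before expansion (nothing shared), before
PCR (shared mutant library and abundances) or before sequencing (shared
read means), reproducing the qualitative noise ordering of replicate
designs split at those stages.

Default conditions (chosen once as the study conditions): insertion rate
0.12 bp^-1 at the centromere and 0.067 bp^-1 on the plateau; `t = 10`
generations; bottleneck of 20 cells per insertion site on average
(real protocols reseed on the order of tens of cells per mutant);
overdispersion `alpha = 0.1` for end-to-end tests; gene lengths uniform
on 300–4000 bp; essential genes get `mu = 0` in the central 80% with a
linear ramp to wild type across the outer 10% — the minimal mechanism for
the U-shaped read profile of essential genes; other disruptions are
near-neutral (`mu ~ N(1, 0.05)`) with a 20% deleterious fraction uniform
on 0.1–0.9, a unimodal fitness spectrum with a low-fitness tail.

The true rate decays **quadratically** to the plateau, reaching it with
zero slope at 200 kb. This shape was chosen because its cumulative curve
is piecewise cubic — the functional family the bias fit assumes — making
the simulation a proper recovery test of the estimator. Shapes with a
kink or faster-than-cubic curvature (linear or sharp-exponential decay)
leave the cubic fit with a systematic derivative misfit that is a
property of the chosen truth, not of the estimator.

What the simulator does **not** emulate: sequence content (restriction
sites, barcodes, mappability), alignment artefacts, chromatin or
nucleotide insertion preferences beyond the centromere effect, secondary
mutations, and cycle-level PCR jackpots. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to those real-data complications.

Problem sizes in the tests and the acceptance script are desk-scale by
design: 2–6 chromosomes with 200–450 kb arms and 30–600 genes (~1e5
insertion sites, ~3e6 reads) rather than the ~12 Mb yeast genome at ~1e8
reads. At these sizes the end-to-end rank correlation with truth is
~0.98 and simulated replicate pairs correlate at ~0.97, mirroring the
reproducibility regime the method targets.

## Known limitations

* Median normalisation assumes a unimodal, mostly-neutral fitness
  spectrum; it is unreliable for multimodal spectra.
* The expected-count model corrects only the centromere bias; the fitted
  rate absorbs the genome-wide average of sites invisible because their
  mutants died (essential-gene dropout), so `E - O` for healthy genes
  centers slightly below the ideal zero when a large genome fraction is
  essential.
* A whole gene gets one fitness value; domain-wise (sub-gene) effects are
  averaged over, and no attempt is made to cluster insertions by domain.
* The per-gene SE describes read-count uncertainty, not the full
  uncertainty of the normalised fitness.
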