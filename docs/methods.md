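# Methods

## Model

A drug's DILI phenotype is treated as the joint empirical distribution
of three onset features — latency (days), R-value, and AST/ALT ratio —
over a curated series of bona fide cases attributed to that drug.  The
working assumption is that a candidate case is more likely to be caused
by the drug the closer its feature values sit to the core of that
distribution.  Host factors (age, sex, HLA genotype, comorbidity) are
deliberately outside the model; dechallenge kinetics and serial labs are
likewise out of scope — only onset values enter.

Each feature's marginal is summarised by nine empirical quantile knots
(probabilities 0, .10, .15, .25, .50, .75, .85, .90, 1) and two outlier
fences.  Scoring is ordinal: 20 points inside the closed IQR, 10/5/0 in
successively outer bands, −5 outside the observed range, −10 when also
beyond a fence.  One feature per drug pair is doubled (weighting), so a
case score spans −40…80.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `percentile_convention` | `type7` | quantile estimator: linear interpolation at p·(n−1)+1; `type6` (p·(n+1)) available. Type 7 is the numpy/R default and fully deterministic. |
| `outlier_k` | 1.5 | fences at min − k·IQR and max + k·IQR. The source material's exact outlier definition is not reproducible from the available text; an IQR-scaled margin is the standard robust reconstruction and is configurable for that reason. |
| `degenerate_epsilon` | 0 | absolute fence margin when IQR = 0 (all knots equal). 0 means a degenerate phenotype never flags outliers; off-centre values are merely outside-range (−5). |
| `ast_alt_uln_normalized` | off | AST/ALT on raw activities (the conventional De Ritis ratio). The ULN-normalised variant needs an AST ULN and is provided in case a source series used it. |
| `round_latency` | off | latencies are accepted as real days; rounding is opt-in. |
| competing-cause rubric | 5 levels, 25/12/0/−12/−25 | spans the fixed −25…25 range; the ladder itself is a package default, not a validated clinical rubric, and is config-replaceable. |
| hepatotoxicity rubric | 3 levels, 0/10/20 | same caveat, range 0…20. |

## Numerical and design choices

**Band boundaries are closed toward the centre.**  A value exactly at a
knot takes the more central band (a value at p25 scores 20, at p15
scores 10, at the minimum 0).  Ties at knots are common in small series;
resolving them toward the centre is stable and matches the reading of
"within the IQR".  Outlier status is strictly beyond a fence, so a value
exactly on the fence is not an outlier.

**The three deduction rows are mutually consistent** by treating the
standalone −5 "outlier" row as the increment stacked on outside-range
(−5), giving −10 for "both".  If fences are manually configured tighter
than the observed range, an in-range value beyond a fence earns the
−5 outlier-within outcome, so every row of the allocation table is
reachable.

**U convention.**  Mann-Whitney results report min(U1, U2), so smaller
U always means greater separation and U = 0 means disjoint samples.
Ties get midranks; p-values are two-sided, from the exact null
distribution when n1·n2 ≤ 400 with no ties, else from the tie-corrected
normal approximation (scipy).  Weighting ties on minimal U break by the
fixed priority latency > R-value > AST/ALT ratio — latency is the most
used discriminator in practice, and determinism matters more than the
choice itself.

**Trend test.**  The single-stratum linear-by-linear form is used:
scores are binned at fixed global 5-point edges (bin = ⌊score/5⌋), and
χ² = (N−1)·r² where r is the Pearson correlation between group
indicator and bin score.  The statistic is invariant under positive
affine transforms of the bin scores, so bin index versus bin lower edge
is immaterial; empty bins drop out of the correlation automatically.
Degenerate inputs (all scores in one bin) return statistic 0, p 1, with
a flag, and the CLI signals them with exit code 3.

**Medians** everywhere use the ordinary sample median, which every
supported quantile convention shares at p = 0.5.

## Synthetic data

The generator draws i.i.d. cases by inverse-CDF sampling through the
piecewise-linear quantile function interpolating a phenotype's nine
knots, independently per feature (no inter-feature correlations are
published for the four fixture drugs; a Gaussian-copula hook exists,
off by default, for sensitivity analyses).  Samples never leave
[min, max], and empirical quantiles converge to the knots as n grows.

Default cohort sizes are the published series sizes (cyproterone 22,
AMX/CLA 35, cefazolin 19, *Polygonum multiflorum* 18).  The fixture
phenotypes carry the published median/IQR/range verbatim; the unprinted
p10/p15/p85/p90 knots are filled linearly in probability and flagged
`interpolated`.  The *Polygonum* AST/ALT IQR is printed descending
(0.4–0.3) in the source; rather than silently repairing it, the fixture
flags it inconsistent-in-source and interpolates the IQR knots from the
printed median and range.

What synthetic cohorts do *not* emulate: ties.  Real series have
integer-valued latencies and rounded lab ratios, so many cases tie at
the quartiles and a majority sits inside the *closed* IQR, making the
self-scored median subscore exactly 20.  Continuous tie-free samples put
just under half the cohort inside a closed type-7 IQR, so their
self-scored median subscores land in the 10–20 inner bands instead.
Passing pipeline tests on synthetic cohorts therefore demonstrate the
engine's arithmetic and the separation behaviour, not the exact
published median scores, which depend on the true patient-level values.

Problem sizes in the shipped checks: quantile-recovery runs at
n = 10 000 per drug with a fixed seed; the oracle cross-checks run 500
random cohorts/tables each; pipeline checks use the published cohort
sizes.  A 2 %/5 % relative recovery tolerance at n = 10 000 is only
asserted where it exceeds three analytic sampling standard errors of the
empirical quantile (SE = Q′(p)·√(p(1−p)/n), computed from the knots);
for strongly right-skewed features the empirical median's SE is of the
same order as 2 % of the median, and a single-seed check there would be
uninformative for any correct sampler.

## Limitations

* Phenotypes require ≥ 2 (realistically ≥ 10) well-characterised cases;
  the method cannot assess a drug's first reported case.
* Drugs with overlapping phenotypes (e.g. the two cephalosporin-class
  antibiotics among the fixtures) are not separable by construction.
* Scores are ordinal points, not calibrated causality probabilities.
* The outlier fence and the extension rubrics are documented
  reconstructions/defaults, configurable pending authoritative
  definitions.
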