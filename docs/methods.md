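# Methods

This note records the modelling choices behind `agonet`: what each stage
computes, the conventions adopted where several are defensible, what the
synthetic herd generator does and does not emulate, and the numerical
details that matter for reproducing results.

## Networks

A pen's network has one node per roster member — animals that never
engaged in aggression remain as isolates, so the node count always equals
the pen size (this matters because every Freeman normalisation is
size-specific; a 14-pig pen is normalised with n = 14).

Three behaviour classes are built from the same event log. Fighting is
reciprocal by definition (both animals bite/push/head-knock), so fight
edges are undirected even though the log records an initiator. Bullying is
unreciprocated and keeps its direction, initiator → receiver. The combined
network pools both classes and is undirected, since mixing directed and
undirected edges inside one metric is undefined. Repeated interactions
between a pair accumulate into a single edge's weight and total duration,
but **all centrality computation happens on the binary adjacency**: degree
is the number of distinct partners, shortest paths are unweighted. Weights
and durations are retained for reporting and export only.

## Centralities and centralisation

Freeman centralisation Σ(C_max − C_i) / max-possible-sum, with the
theoretical maxima tabulated in `freeman_centralisation`'s docstring.
Conventions worth spelling out:

- **Betweenness** uses Brandes' dependency accumulation; undirected pairs
  are counted once (a path A–B–C gives the middle node betweenness 1).
  Unreachable pairs contribute nothing.
- **Eigenvector** scores are the dominant eigenvector of the symmetrised
  adjacency, computed on the largest connected component by a shifted
  power iteration ((A + I)x, tolerance 1e−10 — the shift prevents
  oscillation on bipartite components); smaller components and isolates
  score 0, and scores are rescaled so the maximum is 1. The centralisation
  denominator is n − 2, the sum of differences attained by a single
  connected pair plus isolates. This is the convention of igraph's
  `centr_eigen`; under it a star does *not* attain 1 (its leaves keep
  positive scores ≈ (n−1)^{−1/2}). Degree, betweenness and closeness
  centralisation do attain exactly 1 on a star.
- **Closeness** uses the Wasserman–Faust range-adjusted form
  (r/(n−1))·(r/Σd) with r the number of reachable others. On connected
  networks this is ordinary normalised closeness; on disconnected ones the
  r/(n−1) factor prevents tiny components from producing scores of 1,
  which would push centralisation above 1. Directed closeness (bullying
  networks) measures outward reach and is normalised by n − 1, the value
  attained by an out-star.
- **Largest clique** is found by Bron–Kerbosch with pivoting over bitset
  node masks, with a simple bound-based prune; directed networks are
  symmetrised first. An edgeless pen has clique size 1.
- Edgeless (degenerate) pens report every centralisation as 0 together
  with a `degenerate` flag, rather than missing values, so downstream
  joins never drop pens.

## Dyadic traits

Six per-pig summaries of direct interactions: mean bout duration (fights
and bullying pooled), total fight duration, number of fights (regardless
of initiator), proportion of fight *time* spent in injurious fighting,
and bullying duration given / received. Injurious fighting is a bite rate
of at least 1 per 3 s; the "approximate" field rule is made exact with an
inclusive boundary (3 s with 1 bite counts). The injurious proportion is
time-weighted, not bout-weighted. Pen means divide by the full roster
size, so inactive pigs dilute the mean; a pen with any fight lacking a
bite count reports the injurious proportion as missing with a warning.

## The statistical procedure

**Partial model.** Pen-mean lesion count ~ breed + sex + mean weight +
number of aggressive interactions, with batch as a random intercept,
fitted by REML (statsmodels `MixedLM`). Acute responses are pen means of
per-pig (24 h − pre-mix) differences and may be negative; chronic (3 wk)
responses are raw pen means, not baseline-adjusted. Factors with a single
observed level are dropped with a warning; with a single batch the model
reduces to OLS; if the REML information matrix is singular (tiny herds) a
derivative-free optimiser is tried before falling back to OLS.

Residuals passed to the stepwise stage are **conditional** (batch BLUP
subtracted), so selection sees only variation unexplained by fixed
effects *and* batch. Marginal residuals are available via
`ModelFit.residuals("marginal")`.

**Stepwise.** Classic entry/stay selection on the residuals with
slentry = slstay = 0.15 (the long-standing default of stepwise
implementations in commercial statistics packages; configurable). At each
step the smallest-p candidate enters if p < slentry, then any included
trait with p > slstay leaves. A step that would revisit a previous model
state stops the iteration, so cycling is impossible. Candidates whose VIF
against the current model exceeds 10 are skipped with a collinearity
warning. A model that already fits the residuals to numerical precision
accepts no further terms.

**Full model.** The partial model plus the selected traits. Fit statistics:
RMSE = √(residual variance); AIC = −2ℓ + 2k computed from the REML
log-likelihood with k counting fixed effects plus both variance
components (statsmodels leaves AIC undefined under REML; comparisons are
only meaningful between models with identical random structure, which
holds here); R² in the two variance-explained senses for mixed models —
marginal (fixed effects only, the headline number) and conditional (fixed
plus batch). VIFs are reported for every non-intercept column with a
warning above 10.

**Permutation verification.** The trait column is shuffled across pen
labels — outcomes, covariates and the other traits stay put — and the
coefficient refitted 5000 times. Refits freeze the variance components at
the observed REML estimates and re-estimate coefficients by GLS
(equivalently: whiten by V^{−1/2}, project out the other columns, take
the one-dimensional regression coefficient). This is both the literal
"keep all other effects stable" reading and roughly two orders of
magnitude faster than re-running REML per replicate; to first order the
permuted-coefficient null is unchanged because permutation breaks any
trait–outcome association while V does not involve the trait.

Let q = fraction of permutations whose coefficient lies strictly below the
observed one (ties count against the observed value). The significance
verdict uses the symmetric percentile rule: significant iff the fraction
of permuted coefficients *greater* than the observed is below 2.5% or
above 97.5%. Alongside the conventional two-sided p = 2·min(q, 1−q), the
result also reports the one-sided textbook formula "q, subtracted from 1
for negative coefficients" as `paper_literal_p`; note that the formula
approaches 1, not 0, for strongly significant coefficients of either
sign, so it is reported for completeness but never drives the verdict.

## Synthetic herd generator

The generator emulates the study design the pipeline assumes: 78 pens of
15 pigs (3 from each of 5 litters; optionally one 14-pig pen), single sex
and breed per pen with a 60/40 purebred/crossbred pen mix, weights
N(27.6, 5.6²) kg, pens striped evenly over 14 batches. Per-pen fight and
bullying counts are zero-truncated normal draws with means 62.38 (SD 24)
and 57 (SD 26.4), rounded to integers.

Event structure uses a one-parameter attachment scheme: with probability
`attachment_skew` (default 0.3) the first participant is the pen's
designated top aggressor, otherwise uniform; the partner is uniform. At
skew 1 one pig joins every event (a star-like, maximally centralised
pen); at 0 partners are uniform. Fight durations are lognormal with
median 15 s (bullying 8 s), floored at 1 s — chosen as a realistic bout
scale; nothing downstream is sensitive to the shape. A fraction
(default 0.2) of fights is fought at an injurious bite rate, with bite
counts rounded so the classification survives rounding.

Lesions are planted linearly at the pen-mean level. For each region,
24 h delta = intercept + batch + β_dur·(mean fight duration − 15 s) +
noise; 3 wk raw = intercept + breed + batch + β_clique·(clique − 4.5) +
β_betw·(betweenness − 0.15) + noise. Defaults: β_clique = −2 lesions per
clique member, β_betw = +15 lesions per unit centralisation (≈ +1.2
lesions over the observed centralisation range), β_dur = +0.2 lesions per
second, batch SD 1.5, residual SD 2, with intercepts on the scale of
typical post-mixing lesion tables (acute anterior ≈ 18, chronic
anterior/central ≈ 10, posterior ≈ 4). Effects are centred on reference
trait values so changing an effect size does not move the overall lesion
level. `HerdConfig.null()` zeroes every planted effect for calibration
studies. Pen means are disaggregated to pigs by a multinomial split with
Dirichlet(5) shares — mildly overdispersed, and purely cosmetic since the
analysis consumes pen means; pre-mixing counts are small Poisson(2)
draws, present only to exercise the baseline subtraction.

What a green test on this generator does establish: that the pipeline
recovers planted pen-level effects with correct signs at realistic effect
sizes, that its permutation rule holds its nominal type-I error on null
herds, and that every metric equals an independent oracle. What it does
not establish: anything about real lesion-count distributions (counts are
not Poisson-like at the pen level here), within-day temporal dynamics of
hierarchy formation, sex-specific behaviour, or the magnitude of effects
in real herds.

## Numerical details and limitations

- All randomness flows from a single `numpy` Generator per entry point;
  identical config + seed gives byte-identical outputs.
- Centralisation values are snapped into [0,1] only against float
  round-off (tolerance 1e−6); a genuine violation raises.
- Eigenvector iteration caps at 10⁴ iterations at tolerance 1e−10 and is
  cross-checked against dense eigendecomposition in tests.
- Stepwise inference is selective: p-values of selected traits in the
  full model are optimistic, which is precisely why the permutation
  verification exists. The null selection rate is measured, not hidden
  (see the binomial-expectation test).
- No multiple-testing correction is applied across the eight
  region × timepoint responses, matching standard practice for this
  design; interpret across-response patterns accordingly.
- Generalised (count) models are out of scope; responses are pen means
  treated as Gaussian.
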