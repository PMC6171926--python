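# agonet

Pen-level social network analysis of post-mixing aggression in pigs.

When unfamiliar pigs are mixed into a pen they fight to establish dominance
relationships, and both the acute (24 h) and chronic (3 week) skin-lesion
counts vary enormously between pens in ways that simple dyadic behaviour
summaries (how long pigs fought, how often) do not explain. `agonet`
implements the pen-network approach to this problem: every aggressive
interaction recorded in the first 24 h after mixing becomes an edge in a
per-pen *fighting* (reciprocal, undirected), *bullying* (directed
initiator → receiver) or *combined* network, with non-aggressive pen
members retained as isolates. Pen-level network properties — Freeman
centralisation of degree, betweenness, eigenvector and closeness
centrality, and the size of the largest clique — are then tested as
predictors of pen-mean lesion counts alongside the classical dyadic traits.

The audience is behavioural scientists and veterinary epidemiologists with
event-coded aggression logs and lesion counts in CSV form.

## The model

For individual centrality scores $C_i$ in a pen of $n$ animals, Freeman
centralisation is

$$C^* = \frac{\sum_{i=1}^{n} (C_{\max} - C_i)}{\max \sum_{i=1}^{n}(C_{\max} - C_i)}$$

where the denominator is the largest attainable sum of differences in any
network of the same size (for undirected degree $(n-1)(n-2)$, betweenness
$(n-1)^2(n-2)/2$, closeness $(n-1)(n-2)/(2n-3)$; see
`agonet.metrics.freeman_centralisation`). A maximally centralised "star"
pen scores 1, a perfectly even "ring" pen scores 0.

The statistical procedure has three stages per lesion response
(timepoint × body region, with 24 h responses baseline-subtracted):

1. **Partial model** — a REML linear mixed model of the pen-mean lesion
   count on breed, sex, mean pen weight and the number of aggressive
   interactions, with experimental batch as a random intercept.
2. **Stepwise regression** of the partial-model residuals on the candidate
   network and dyadic traits (entry/stay thresholds 0.15, VIF-guarded).
3. **Full model** — the partial model plus the selected traits, reporting
   RMSE, AIC, marginal/conditional R² and VIF.

Selected network traits are verified by a permutation test: the trait is
shuffled across pens 5000 times with everything else held fixed, and the
observed coefficient is judged against the permuted-coefficient
distribution with the symmetric 2.5%/97.5% percentile rule.

Because the original farm data are not publicly deposited, the package
ships a synthetic herd generator (`agonet.simulate`) reproducing the study
design — 78 single-sex single-breed pens of 15 pigs (3 pigs from each of 5
litters), weights ≈ N(27.6, 5.6²) kg, ≈62 fights and ≈57 bullying bouts
per pen per 24 h — with lesion counts generated from a planted linear
model on the network traits, so the whole pipeline is validated by
parameter recovery.

## Worked example

```bash
agonet simulate --seed 1 --out-dir demo   # 1,170 pigs, ~9,800 events
```

```python
import warnings; warnings.simplefilter("ignore")
from agonet.io import read_roster, read_events, read_lesions
from agonet.models import *
from agonet.pipeline import candidate_trait_table
from agonet.permutation import permutation_test

roster = read_roster("demo/roster.csv")
events = read_events("demo/events.csv")
lesions = read_lesions("demo/lesions.csv")
out = pen_lesion_outcomes(lesions, roster)
cov = pen_covariate_table(roster, events)
cand, _, network_names, _ = candidate_trait_table(roster, events)

partial = fit_partial_model(out, cov, "3wk", "total")
step = stepwise_select(partial.residuals(), cand.set_index("pen_id")[network_names])
full = fit_full_model(out, cov, cand, step.selected, "3wk", "total")
perm = permutation_test(out, cov, cand, "fight_betweenness_centralisation",
                        selected=step.selected, timepoint="3wk", region="total",
                        n_perm=5000, seed=1)
```

Output for this seed:

```
partial:  RMSE=7.00  R2m=0.33  AIC=544.9
stepwise selected: ['fight_betweenness_centralisation', 'bully_largest_clique_size',
                    'fight_largest_clique_size', 'bully_in_degree_centralisation',
                    'bully_out_degree_centralisation']
full:     RMSE=2.81  R2m=0.74  AIC=421.5
  fight_betweenness_centralisation: 47.11 (SE 5.24), p=2.582e-19
  fight_largest_clique_size: -4.98 (SE 0.66), p=5.48e-14
permutation (fight_betweenness_centralisation): coef=47.11, q=1.0000,
  two-sided p=0.0000, significant=True
```

Reading this: the husbandry covariates alone leave two thirds of the
between-pen variance in chronic (3 wk) lesions unexplained. The stepwise
stage pulls in the fighting-network structure; the fitted clique
coefficient is negative (pens whose first-day fights formed a large fully
connected subgroup carry fewer lesions three weeks later — here ≈ −5
lesions per extra clique member on the whole-body total, the planted
per-region effect of −2 summed over three regions), while betweenness
centralisation is positive (fragmented pens bridged by few animals carry
more). The permutation verdict confirms the betweenness coefficient sits
above all 5000 permuted coefficients. The correlated bully-network traits
that slip into the selection are flagged by their large p-values in the
full model.

The same analysis end-to-end, for all eight responses:

```bash
agonet run --roster demo/roster.csv --events demo/events.csv \
           --lesions demo/lesions.csv --n-perm 5000 --seed 1 --out-dir demo_out
agonet report --bundle demo_out/report.json
```

## Acceptance script

`scripts/acceptance.py` rebuilds the two self-contained reference
networks — the 15-node star and ring — from scratch, runs the package's
degree-centrality and Freeman-centralisation routines on them, and writes
the measured centralisations to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Broader validation (oracle equivalence of every metric, permutation-rule
calibration on 500 null herds, planted-effect recovery on 200 herds,
generator calibration) lives in `tests/test_acceptance.py`.
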