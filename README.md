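# modeljump

Bayesian site-model averaging for nucleotide alignments by reversible-jump
MCMC.

## The problem

A Bayesian phylogenetic analysis of nucleotide sequences requires a *site
model*: a substitution model (which of the six exchangeability rates r_AC,
r_AG, r_AT, r_CG, r_CT, r_GT are tied together), whether rates vary across
sites (a discrete-gamma mixture with shape α), whether a proportion p_inv of
sites is invariable, and whether base frequencies π are equal or estimated.
The common practice of picking one site model with a separate
likelihood-based tool and conditioning the analysis on it discards model
uncertainty and is circular (the selection step itself needs a tree).

modeljump instead treats the site model as a random variable and samples it
jointly with the other parameters, using trans-dimensional
(Metropolis–Hastings–Green) proposals.  The posterior then *averages* over
site models — or, read the other way, gives posterior probabilities for each
model, from which credible sets of models are formed.

## The model space

A substitution model is a grouping of the six rates written as a
restricted-growth code: `111111` ties all rates (JC), `121121` ties the four
transversions and the two transitions (HKY), `123456` is GTR.  Three spaces
are supported:

* **all** — every grouping: 203 models;
* **tstv** — groupings that never mix a transition with a transversion rate
  (plus `111111`): 31 models;
* **named** — a nested 9-model ladder JC → HKY → TN93/K81 → … → GTR.

Models form a graph whose edges split one rate group in two; the sampler
walks this graph with split/merge moves, and within a model the rates move
on the constraint surface Σ r = 6 (which fixes their scale).  Priors:
uniform over models (or uniform over parameter counts, giving JC and GTR 1/6
each), flat or transition/transversion-informed rate priors,
Dirichlet(4,4,4,4) frequencies, Exponential(1) for α, Beta(1,4) for p_inv,
and an independent Bernoulli(1/2) for each of the three indicators.

## Worked example

Simulate 10,000 sites on a fixed three-taxon clock tree under a site model
drawn from the prior with gamma heterogeneity forced on (the truth happens
to be HKY, transversion rate 1.062, transition rate 0.875, α = 0.737,
unequal frequencies), then analyse the alignment over the 31-model ts/tv
space and summarize the trace:

```bash
modeljump simulate --tree "(A:0.2,(B:0.15,C:0.15):0.05);" --n-sites 10000 \
    --cell "+G" --unequal-freqs --seed 23 --out-prefix demo/sim
modeljump run --alignment demo/sim.fasta --tree demo/sim.nwk \
    --model-set tstv --chain-length 30000 --log-every 15 --seed 23 \
    --out demo/trace.tsv
modeljump summarize --trace demo/trace.tsv --out-prefix demo/post
```

which prints

```
[modeljump] 3 taxa, 10000 sites (64 patterns), 31 models
[modeljump] trace written to demo/trace.tsv
[modeljump] credible set: 20 models (mass 0.963); site-model variants in set: +G, +G+I
```

`demo/post.models.tsv` ranks the models — the generating model `121121`
(HKY) is in the 95% credible set with posterior 0.154, behind its neighbour
`121321` (0.188); with three taxa many groupings remain plausible, which is
exactly the uncertainty that model averaging propagates.
`demo/post.hpd.tsv` gives posterior means and 95% HPD intervals; here the
transversion-rate estimates bracket 1.06 and the transition rates 0.875, the
gamma-shape posterior (conditioned on the +G part of the sample) has mean
0.90 with HPD (0.69, 1.28) covering the true 0.737, and the heterogeneity
indicator itself is decisive: P(+G) = 1.0.

The library mirrors the CLI: `ModelSet.create`, `compress_patterns`,
`run_chain`, `credible_model_set`, `hpd_interval`, `coverage_report`, and
the simulators `simulate_yule_tree` / `simulate_alignment` /
`run_validation_study` are the main entry points.

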