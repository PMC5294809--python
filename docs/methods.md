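# Methods

## State space

The sampled state is (M, R, γ, α, ι, p_inv, φ, π) where M is a grouping of
the six exchangeability rates (a set partition, written as a
restricted-growth code), R the per-group rates, γ/ι/φ binary indicators for
gamma rate heterogeneity, an invariable-site category and estimated base
frequencies, α > 0 the gamma shape, p_inv ∈ (0,1), and π a point on the
4-simplex (pinned at (¼,¼,¼,¼) while φ = 0).  α, p_inv and π are present in
every state but inert while their indicator is off; their priors enter the
posterior only when the indicator is on, and birth moves redraw them, so the
inert values never influence anything.

Identifiability of the relative rates is enforced by the constraint
Σ n_g r_g = 6 (n_g = group size), i.e. the six expanded rates always sum
to 6.  The rate matrix Q_ij = π_j r_ij is additionally normalized to unit
expected rate, so branch lengths are expected substitutions per site under
every sampled site model.

## Priors and their defaults

| component | prior | default | why |
|---|---|---|---|
| model M | uniform over the set, or uniform over dof classes | uniform | the dof-uniform option gives JC and GTR 1/6 each |
| rates R | flat on the constraint surface, or ts/tv-informed | flat | see below |
| transition rates (ts/tv prior) | log-normal, real-space mean 1, sd(log) 1.25 | — | transitions empirically faster |
| transversion rates (ts/tv prior) | exponential, mean 1 | — | |
| frequencies π | Dirichlet(4,4,4,4) | — | mild concentration; P(min π < 0.05) ≈ 2.2% |
| α | Exponential(mean 1) | — | |
| p_inv | Beta(1,4) | — | mean 0.2 |
| each indicator | Bernoulli(½) | — | the four variants plain/+G/+I/+G+I equiprobable a priori |

The gamma mixture uses k = 4 equal-probability categories whose rates are
the conditional means of the quantile bins of Gamma(α, 1/α) (the
"mean" discretization), so the category rates average exactly 1.  When the
invariable category is present its weight is p_inv at rate 0 and the
non-zero rates are inflated by 1/(1−p_inv), keeping the overall mean rate at
1 so branch lengths retain their meaning.

## The rate prior on the constraint surface, and the split/merge factor

Work in mass coordinates s_g = n_g r_g, in which the constraint is the
scaled simplex {s_g > 0, Σ s_g = 6}.  The flat rate prior is the
**normalized** uniform density on that simplex: log(G−1)! − (G−1)·log 6 for
a model with G groups.  Normalizing per model matters: it is what makes the
marginal posterior probability of each model equal its model prior when the
likelihood is flat, i.e. what makes prior sampling exact.

A split of a group of size n = n_i + n_j with rate r chooses a child model
uniformly among the graph children, draws u ~ U(−n_i r, n_j r) and sets
r_i = r + u/n_i, r_j = r − u/n_j; equivalently the new mass s_i lands
uniformly on (0, nr).  The reverse merge (the size-weighted mean rate) is
deterministic given the chosen parent.  In the mass chart the
dimension-matching map has unit Jacobian, so with the standard
Metropolis–Hastings–Green rule the non-posterior factor of a split from M to
M′ is

    q(back)/q(forward) = nr · |split(M)| / |merge(M′)|

and the normalized flat priors contribute the remaining factor G/6 through
the prior ratio.  We derived this from first principles because the
commonly quoted proposal-ratio/Jacobian pair for this move (density term
1/(r(n_i+n_j)) with Jacobian (n_i+n_j)/(n_i n_j)) mixes the two orientation
conventions and, checked by hand on a three-rate toy space, does not leave a
flat conditional prior invariant when the two fragment sizes differ.  The
decisive empirical check is `test_prior_sampling_chain_is_exact`: with the
likelihood forced constant, model frequencies over the 31-model space are
uniform to a chi-square test on 10⁵ retained samples, and every continuous
marginal matches its prior by KS test.

At the boundary models the move proposes the current state (nothing to
split at GTR, nothing to merge at JC); these self-moves are required for
uniform sampling.

Under the ts/tv-informed rate prior the density on the surface is the
product of the six per-position densities, **unnormalized** per model (the
normalizers have no closed form).  Within a model only ratios matter, so
estimation is unaffected; across models the unknown normalizers perturb the
model marginals slightly.  The flat prior, which is the default and the one
used for calibration studies, has no such caveat.

## Other proposals

* **Rate exchange** — transfer mass m ~ U(0, δ) between two uniformly
  chosen groups: r_i′ = r_i − m/n_i, r_j′ = r_j + m/n_j; reject if r_i′ < 0.
  Drawing the *mass* uniformly makes the kernel symmetric (Hastings 1)
  for any group sizes; drawing u uniformly in the first group's rate
  coordinate would be symmetric only for equal sizes.
* **Indicator birth/death** — flip γ (or ι, φ); birth draws α (p_inv, π)
  fresh from its prior, so prior × Hastings cancels and acceptance reduces
  to the indicator-prior ratio times the likelihood ratio.
* **α scale** — multiplicative kernel s ~ U(sf, 1/sf), Hastings 1/s; fires
  only while γ = 1.
* **p_inv** — Gaussian random walk in logit space (respects the (0,1)
  support) with the change-of-variables Hastings term; fires only while
  ι = 1.
* **Frequency walk** — symmetric mass exchange between two components of π;
  fires only while φ = 1.

Default operator weights: split 1, merge 1, rate exchange 2, each
indicator toggle 1, α scale 1, p_inv walk 1, frequency walk 1.  δ, the walk
step and the scale factors are adapted toward acceptance 0.234 by
Robbins–Monro during burn-in (10% of the chain) and frozen afterwards to
preserve detailed balance.

## Likelihood

Felsenstein pruning on compressed site patterns, with per-pattern scaling
against underflow.  Transition matrices come from the symmetrized
eigendecomposition of the reversible Q (exact, and vectorized over branches
and categories).  IUPAC ambiguity codes become 0/1 leaf partial vectors;
gaps are fully ambiguous.  The zero-rate category is never pruned: a
pattern contributes p_inv·Σ π_x over the bases x compatible with the column
being constant (0 if none), which is exact.  Because toggling γ switches
between a 1-category and a k-category evaluation, the likelihood front-end
keeps one cache per configuration, so a toggle never invalidates both and
toggling back is a cache hit.

An optional strict-clock mode samples internal-node heights on a fixed
ultrametric topology (uniform node slides and a root-height scale move)
under a fixed-rate Yule prior.  It exists to reproduce tree/site-model
co-estimation; full topology search is out of scope.

## Simulator

`simulate_yule_tree` draws a pure-birth tree conditioned on n tips: with k
lineages the inter-event time is Exponential(kλ), giving expected root
height (1/λ)Σ_{k=2..n} 1/k.  `simulate_alignment` draws a rate category per
site, copies a single stationary draw to all taxa for zero-rate sites, and
otherwise evolves the root draw down the tree with P(t) = exp(Qt) computed
by scipy's expm — a deliberately independent code path from the pruning
engine's eigendecomposition.  Chance-invariant columns are left in the
alignment.  Validation truth draws clamp the indicators to a design cell
(plain/+G/+I/+G+I × equal/unequal frequencies); all other parameters come
from their priors.

What the generator does **not** emulate: indels and alignment error,
among-lineage rate variation (the clock is strict with rate 1), selection,
and site-to-site dependence.  Passing calibration here shows the sampler
targets its own model correctly — not that the model fits any particular
real alignment.

## Summaries

The 95% credible model set is the smallest set of models with posterior
mass ≥ 0.95 (ties broken by model string); the analogous construction over
the joint (γ, ι) frequencies gives the site-model-variant credible set.
HPD intervals are the shortest window of ⌈0.95·n⌉ consecutive order
statistics.  α and p_inv are summarized, and their coverage scored, on the
part of the sample where the true site-model variant is being visited.
Frequency coverage is scored only on replicates generated with unequal
frequencies; for equal-frequency truths the equal-frequency indicator is
scored instead (whether the posterior leaves it ≥ 5% probability) — one of
several defensible conventions, stated here rather than asserted as
canonical.  Summaries discard a configurable burn-in fraction (default
10%).

## Study designs and problem sizes

* **Prior-sampling check** — 3.15M steps thinned by 30 after burn-in to 10⁵
  retained samples, with split/merge weights raised to 3 so the
  model-occupancy autocorrelation time is ~10 steps and the retained
  samples are effectively independent for the chi-square test.
* **Rate recovery** — 20 replicates (half with, half without gamma
  heterogeneity, invariable-sites off, unequal frequencies) of 10,000 sites
  on the tree (A:0.2,(B:0.15,C:0.15):0.05); ts/tv rate priors for both
  truth and analysis; chains of 30,000 steps.  Headline figure: per-rate R²
  between true and posterior-mean rates (all six > 0.99).
* **Coverage** — two cells (plain and +G, unequal frequencies) × 25
  replicates of 2,000 sites, chains of 24,000 steps, flat rate prior for
  both truth draw and analysis so the generating distribution *is* the
  chain's prior and 95% coverage is the exact expectation.  Each scored
  quantity is accepted iff its hit count is consistent with Binomial(25,
  0.95) at the 1% level (≥ 21 hits).
* **Yule heights** — 10⁴ five-taxon trees, λ from the log-normal prior
  (real-space mean 5.5, sd of log 0.048); mean root height ≈ 0.233.

Truth draws under the ts/tv rate prior rescale unconstrained draws onto the
sum-to-6 surface — an approximation to the exact conditional (the flat
prior is sampled exactly as 6·Dirichlet(1,…,1) in mass coordinates).

## Numerical choices

Gamma bin means via the regularized incomplete gamma function (then
renormalized to kill last-bit drift); transition probabilities clipped at 0
after the eigendecomposition round trip; per-pattern log-scale
accumulators in the pruning; hand-written log densities (exponential,
log-normal, beta, symmetric Dirichlet) in the MCMC hot path, checked
against scipy in the tests; all chains driven by a single numpy Generator
so runs are bit-reproducible from the seed.

## Known limitations

Three-or-more-taxon rooted trees only (the two-taxon case works but the
root placement is arbitrary); no partitioned alignments; no codon or
amino-acid model spaces; the ts/tv rate prior's per-model normalizers are
not computed (see above); the coverage convention for equal-frequency cells
is a package choice; tree sampling is deliberately minimal.
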