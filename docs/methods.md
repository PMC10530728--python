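# Methods

## Measurement-bias model

`microbias` treats the observed composition of a sequencing sample as a
multiplicatively distorted image of the true composition. For sample *i*
and taxon *j*,

    log p_ij = log pi_ij + gamma_j + eta_ij + alpha_i,
    eta_ij   = sum_{j' != j} theta[j, j'] * pi_ij',

where `p_ij` is the expected observed relative abundance, `pi_ij` the true
relative abundance, `gamma_j` a composition-independent main-effect bias,
`eta_ij` the total interaction bias and `alpha_i` the per-sample
normalization that restores the unit-sum constraint. With all
`theta[j, j'] = 0` this is the classical multiplicative bias model under
which ratio-based (compositional) methods can be fully bias-robust; the
interaction term is the departure this package exists to study.

Interaction coefficients are generated relative to the main effects:

    theta[j, j'] = -sign(gamma[j']) * phi * epsilon[j, j'] * |gamma[j]|.

Assumptions built into this construction:

* **Sign opposition.** A taxon that is over-measured (`gamma[j'] > 0`)
  depresses the measured abundance of other taxa, as expected when a
  roughly constant total number of amplicons is sequenced.
* **Scaling with the affected taxon.** The perturbation received by taxon
  *j* scales with `|gamma[j]|`; a taxon measured without main-effect bias
  receives no interaction bias (`sign(0)` is defined as 0 for the same
  reason on the sending side).
* **Asymmetry.** `theta[j, j']` and `theta[j', j]` are drawn independently;
  nothing forces reciprocity.
* **Abundance weighting.** Taxon *j'* perturbs others in proportion to its
  *true post-spike* relative abundance `pi_ij'`, so rare taxa contribute
  little regardless of phi.

`epsilon` is non-negative with unit mean, drawn on the half scale
(`epsilon/2`) from one of two distributions per matrix row *j*:

| scenario | row distribution of epsilon/2 | variance structure |
|---|---|---|
| `S-nondiff` | N(0.5, 0.1²) for all rows | homogeneous, small |
| `S-diff-causal` | Beta(0.5, 0.5) on causal rows, normal elsewhere | trait-linked extra variance (0.125 vs 0.01) |
| `S-diff-half` | Beta(0.5, 0.5) on a random half of rows | large but trait-unrelated |

The N(0.5, 0.1²) law carries ~3e-7 mass below zero; draws are clamped at 0,
preserving the stated non-negative support with negligible distortion.

The conversion `phi_from_presence_ratios` maps estimates from a
*presence*-based interaction model (where the mere presence of *j'* shifts
taxon *j*'s log bias by `theta~[j, j']`) onto the abundance-weighted scale:
when community members share a common relative abundance *p*,
`phi = mean|theta~/gamma| / p`. The package's reference calibration —
mean ratio 0.204 in three-member, equal-proportion mock communities —
gives `phi = 0.612`. Simulations sweep phi over 0–4 around that value;
phi = 0 recovers the pure main-effect model exactly (bit-for-bit, since the
interaction stream is skipped without touching any other stream).

## Data generation

One replicate chains the following steps, each on its own named substream
of the replicate seed, so disabling or modifying one step never perturbs
the draws of another:

1. **Baseline composition.** Each sample's `pi0_i` is Dirichlet with mean
   `pi_bar` and overdispersion `theta_DM` (default 0.02), parameterized as
   concentration `alpha_j = pi_bar_j (1 - theta_DM) / theta_DM` so that
   `Var(pi_j) = pi_bar_j (1 - pi_bar_j) theta_DM`.
2. **Trait and confounder.** Binary traits are balanced (n/2 per group,
   randomly ordered, default n = 100); continuous traits are U[-1, 1]. An
   optional binary confounder accompanies binary traits only:
   Bernoulli(0.2) when T = 0, Bernoulli(0.8) when T = 1.
3. **Causal sets.** Scheme M1 draws 20 causal taxa uniformly from those
   with mean abundance above 0.005, excluding the single most abundant
   taxon; M2 takes the five most abundant taxa. Confounder-associated sets
   are 10 causal + 10 null taxa (M1) or 2 + 3 (M2). All causal taxa share
   one trait effect beta (log fold change on absolute abundance);
   confounder effects default to magnitude beta with alternating signs,
   since no canonical values exist for them. At beta = 0 no taxon is
   causal (the global null) and the recorded causal set is empty.
4. **True abundances.** Exponential tilt of the baseline by
   `exp(beta_j1 T_i + beta_j2 C_i)`, renormalized per sample.
5. **Observed abundances.** Further tilt by `exp(gamma_j + eta_ij)`,
   renormalized; the log of the normalizing denominator is returned as the
   replicate's implicit normalization constant.
6. **Counts.** One multinomial draw per sample at a library size from
   N(10 000, (10 000/3)²) left-truncated at 2 000 (rejection sampling,
   acceptance ~0.992, rounded to the nearest integer — the multinomial
   needs integer totals).

Main-effect biases (`sigma_gamma = 0.8`, giving a 95% fold-change range of
roughly 0.2–5) and epsilon are redrawn for every replicate, averaging the
benchmark over bias configurations just as the Dirichlet baseline averages
over communities; `ReplicateSpec.fixed_gamma` pins gamma instead when a
diagnostic conditions on one bias configuration.

### Synthetic mean-abundance profile

The real upper-respiratory-tract profile behind the default configuration
is external data, so the package synthesizes a stand-in: ranks decay as a
power law (`rank^-1`) with log-normal noise (sigma 0.5), sorted and
normalized, optionally with the leading means pinned to the five published
values (0.105, 0.062, 0.054, 0.050, 0.049). Pinned tails are water-filled
under a cap strictly below (0.999x) the last pinned value, keeping the
vector non-increasing and the pinned head bit-exact — a cap *at* that value
would create ties and could flip the "top five most abundant" selection. A
user-supplied vector (one proportion per line) replaces the synthetic
profile entirely.

The synthetic profile reproduces the dominance structure and the long rare
tail of a real community, which is what drives both the presence filter and
the abundance weighting of interaction biases. It does **not** reproduce
taxon identities, phylogenetic correlation, or the exact rank-abundance
curve of any real dataset, so absolute FDR/sensitivity numbers from it are
indicative rather than portable; the qualitative contrasts (phi sweeps,
scenario contrasts, filter stringency) are the meaningful output.

## Testing protocol and evaluation

The bundled reference procedure mirrors a standard naive compositional
analysis: filter taxa present (count > 0) in fewer than 20% of samples
(boundary kept; a 10% variant matches several published methods' own
filter), choose the most abundant *null* taxon among the kept taxa as the
alr reference (known truth makes this available in simulation; ties break
to the lowest index), add pseudocount 0.5 or 1 to all counts, take
per-taxon log ratios against the reference, run two-sided Wilcoxon
rank-sum tests of the binary trait, and adjust with Benjamini–Hochberg.
Detection is q <= 0.20; the relatively high nominal level suits the small
causal sets. The reference taxon itself is never tested and is excluded
from all denominators. The rank-sum test uses exact enumeration when the
smaller group has at most 10 tie-free observations and the tie-corrected,
continuity-corrected normal approximation otherwise; constant data give
p = 1 by convention. Wilcoxon-based tests are restricted to binary traits;
a continuous trait raises an explicit error rather than silently
dichotomizing.

Per replicate, the false discovery proportion is
`|detected \ causal| / |detected|` (0 when nothing is detected) and
sensitivity is `|detected ∩ causal| / |causal|`. Cell-level empirical FDR
is the mean FDP over replicates; sensitivity is reported as missing (not
0) at beta = 0, where it is undefined. External methods register under a
unique name with the signature `(dataset, level, filter_spec) ->
TestResult`; a replicate on which an adapter raises is logged and excluded
from that method's averages, with the used replicate count reported.

### Seed discipline

A grid replicate's seed is a pure function of `(base_seed, r)` — the cell
coordinates (scenario, phi, beta) do not enter. All cells therefore share
baseline communities, traits, gamma and the normal-row epsilon draws
(common random numbers), which sharpens between-cell contrasts and yields
an exact structural property: `S-nondiff` and `S-diff-causal` produce
identical interaction-bias fields at null taxa of matching replicates,
because each epsilon row has its own child stream and only the causal rows
switch distribution. Causal and confounder sets are drawn once per grid
from a dedicated substream, so within a grid FDR and sensitivity vary only
through sampling noise. Any replicate can be regenerated in isolation.

## Diagnostics

`eta_diagnostics` summarizes the interaction-bias field per taxon: pooled
mean and variance of `eta_ij` across samples and replicates, plus mean
`|gamma_j|`. Two structural facts are worth knowing when reading it.
Averaged over redrawn bias configurations the per-taxon mean of eta tends
to zero, but it converges slowly: conditional on one gamma draw the mean is
offset by `-phi |gamma_j| * sum_j' sign(gamma_j') pi_bar_j'`, a shared term
whose standard deviation across configurations is roughly
`sigma_gamma * sqrt(sum(pi_bar^2))` (~0.1 at the defaults) — "near zero"
relative to the gamma scale of 0.8, not exactly zero. The across-sample
variance of eta is monotone in `|gamma_j|` at fixed phi, which the
diagnostics expose for rank-correlation checks.

## Numerical and design choices

* Presence means count > 0; the filter keeps taxa at exactly the threshold.
* Dirichlet draws renormalize to unit rows at float precision; abundance
  matrices are validated to row sums within 1e-10 (1e-6 tolerance on user
  input to `interaction_bias_field`).
* Epsilon's diagonal is drawn (for stream alignment) but never used; the
  interaction matrix zeroes its diagonal.
* The `S-diff-half` row set is drawn once per replicate from the
  replicate's own stream.
* BH adjustment delegates to `statsmodels.stats.multitest.multipletests`;
  the rank-sum test delegates to `scipy.stats.mannwhitneyu`. Both are
  verified in the test suite against independent brute-force oracles
  (literal step-up enumeration; enumeration over all rank assignments).
* Default replicate count is 200 per cell for desk-scale runs; the
  published-scale 1000 is one configuration flag away. The bundled
  acceptance computations use 500 replicates at J = 200, n = 100, which
  puts the binomial standard error of a global-null FDR estimate near
  0.018 while keeping a full run in seconds.
* Derived integer seeds are masked to < 2^31.

## Limitations

* The interaction model is phenomenological — calibrated in magnitude and
  sign against seven-taxon mock-community evidence, not mechanistically
  derived; real communities may interact differently.
* No zero-inflation beyond what multinomial sampling of rare taxa
  produces; no longitudinal or correlated-sample designs.
* External DA methods are adapters only; nothing is inferred about them
  unless the user attaches implementations.
* Fitting the Dirichlet–multinomial or the bias model to real datasets is
  out of scope; the package consumes, rather than estimates, its
  parameters.
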