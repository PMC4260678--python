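# Methods

## The population model

The unit of inheritance is the cytoplasmic lineage: a maternal line carrying
one mtDNA clade (fixed forever at generation 0 — mtDNA and *Wolbachia* are in
complete cytoplasmic linkage) and one infection state. The population holds a
constant `n_lineages = N` of them, reproducing in non-overlapping
generations, matching the experimental husbandry the package targets. `N` is
the *effective* number of transmitting lineages, not the census count of
flies; the canonical value 75 corresponds to an estimated effective size of
~300 chromosomes (cytoplasmic elements are haploid and maternally
transmitted, so their effective number is about a quarter of the autosomal
chromosome count). Whether this denotes transmitting females or effective
cytoplasmic copies is not distinguishable from the available information;
the simulator treats it as the count of transmitting lineages, which is the
interpretation under which the drift test's binomial kernel is exact.

One generation is, in order:

1. **Selection + incompatibility weighting.** Cytotype `k` receives weight
   `f_k · w_k` (frequency × relative fitness, `w = 1 + s`). If cytoplasmic
   incompatibility is enabled (`ci_intensity > 0`), every *uninfected*
   cytotype's weight is further multiplied by
   `1 − ci_intensity × (infected lineage frequency)` — the standard
   hatch-rate penalty on uninfected mothers crossed to infected males,
   assuming an equal sex ratio. Only unidirectional CI (infected vs
   uninfected) is modelled; bidirectional CI between clades is excluded
   because it has not been demonstrated in *D. melanogaster*. CI is OFF by
   default: it is a beyond-the-core extension for exploring infection-rate
   dynamics, not part of the canonical scenarios.
2. **Wright–Fisher resampling.** `N` offspring are drawn multinomially from
   the normalised weights. With all weights equal this is exactly the
   neutral binomial kernel of the drift test.
3. **Transmission loss.** Each infected offspring loses the infection with
   probability `1 − transmission_fidelity`, moving to an
   uninfected-but-same-mtDNA cytotype (label `<clade>:uninfected`). The
   founding uninfected pool keeps the label `uninfected`; its mtDNA
   background is deliberately unlabelled, since the input frequencies
   specify only an aggregate uninfected fraction.

Generation 0 is integerised by largest-remainder rounding so counts sum to
`N` exactly. Replicates use independent streams spawned from one seed
(`numpy.random.SeedSequence`), so runs are bit-reproducible.

### Canonical scenario defaults (`wolbtrack.scenarios`)

- clades VI / V / I_II_III at 55% / 25% / 20% relative frequency among
  infected lineages (the base-population composition; clades I–III are
  merged because they share most variants);
- infected fraction 53% when the uninfected pool is included;
- `N = 75`, 15 generations ("cold regime"), clade V fitness `1 + s` with
  `s = 0.18`;
- transmission fidelity 1 and CI 0 in the canonical runs (the drift and
  selection analyses condition on relative clade frequencies among infected
  flies, which imperfect transmission does not perturb under equal
  uninfected fitness).

## The observation model

Pool-Seq of the symbiont genome sees only infected flies, so the quantity it
measures is each clade's frequency *relative to the infected fraction*; the
simulator exposes exactly that (`wolbachia_clade_frequencies(relative=True)`).
Per diagnostic SNP and pool, depth is Poisson with the configured mean
(shotgun sampling; overdispersed alternatives are out of scope) and the
diagnostic-allele count is binomial at the owning clade's frequency with a
symmetric per-base error `e` (a true diagnostic read miscalls away with
probability `e`; each other base miscalls toward it with `e/3`). All
non-diagnostic reads carry the reference base. No read-level simulation, no
mapping, no quality scores: the sync count table is the interface.

The default analysis coverage is mean 80× raw with downsampling to 50× —
deep enough that most sites clear the 50× target, which mirrors the
standard practice of equalising coverage across pools before comparing
frequencies.

## Clade-frequency estimation

A diagnostic SNP is an alignment column where one clade group is **fixed**
for an allele that **no other group carries**. Fixation within the group is
required (not just presence) because only then does the pooled allele
frequency equal the clade frequency — the identity the estimator relies on.
Columns containing any N/ambiguity character in any haplotype are excluded.
In a two-group panel every diagnostic column is necessarily diagnostic for
both groups with complementary alleles, so table uniqueness is enforced on
(contig, position, allele), not position alone.

Estimation per pool and clade: downsample each site to the target coverage
by multivariate hypergeometric draw (without replacement, the semantics of
the standard Pool-Seq subsampling tools; a with-replacement option exists
for comparison), compute diagnostic-allele count / target coverage, and
take the median over sites (even counts average the two central values).
Choices worth stating:

- Sites *below* the target are excluded with a warning, never up-sampled —
  up-sampling fabricates precision. No additional per-SNP coverage floor is
  applied beyond the target itself.
- N and deletion counts contribute to the downsampling draw (they are
  reads) but never to the diagnostic numerator; the denominator is the full
  post-downsampling coverage.
- A clade with zero usable SNPs is reported as **missing**, never as zero —
  absence of evidence is not an estimate.
- The median makes the estimate robust to corruption of any minority of a
  clade's SNPs (mismapping, paralogy, residual polymorphism).

The cumulative check sums the clade medians per pool; values inside
[0.9, 1.1] (configurable) pass. A low sum is the signature of a major
unrepresented lineage.

## Drift test

Exact, not simulated: the `(N+1)×(N+1)` binomial transition matrix is raised
to the `t`-th power (`numpy.linalg.matrix_power`, repeated squaring; dense
matrices, practical to `N` of a few thousand) and the start-count row is the
null end-count distribution. Observed frequencies map to counts by rounding
half away from zero.

The two-sided p-value is **twice the directional tail mass**
(`2·P(X ≥ obs)` for an increase, `2·P(X ≤ obs)` for a decrease), capped at
1, with `p = 1` for no change. Doubling the tail, rather than the point
probability, is the conventional reading of a two-sided alternative framed
as "a change at least as pronounced"; it is the more conservative of the
two (the point-mass version would be ~5× smaller here). Absorbing states
contribute to tails — no conditioning on non-fixation — which also makes
the test conservative, as the neutral-calibration test verifies (empirical
rejection at α = 0.05 is ~0.02).

Replicates are combined by **multiplying p-values**: the replicates are
independent populations, so the product is the joint null probability of
all of them changing at least as extremely as observed. A product of
uniforms is stochastically smaller than uniform, so the product is *not*
itself a calibrated p-value; it is reported as defined, and Fisher's
combined test (`−2Σln p` vs χ² with 2k df) is always computed alongside as
the calibrated alternative. A p-value of exactly 0 (possible only in
degenerate settings such as `t = 0` with an observed change) gives Fisher
p = 0 by continuity.

The test ignores any concurrent change in infection rate; no correction is
attempted.

## Selection coefficients

Two formulations, both assuming the focal clade has the same advantage over
every competitor (haploid selection):

- **discrete** (default): `s = [odds(p_t)/odds(p_0)]^{1/t} − 1`, the exact
  inverse of iterating `p' = p(1+s)/(1+ps)` — round-trips with the forward
  recursion to machine precision;
- **logit**: `s = [logit(p_t) − logit(p_0)]/t`, the continuous-time slope,
  equal to `ln(1+s_discrete)` and therefore always slightly smaller.

Both are always reported. Frequencies of exactly 0 or 1 have undefined odds;
the error message suggests a pseudo-frequency, and the pipeline clips
estimates to `[1/(2c), 1 − 1/(2c)]` at working coverage `c` (half a read)
before inversion. For the canonical 0.25 → 0.80 change over 15 generations:
`s = 0.180` (discrete), `0.166` (logit).

## What the tests do and do not show

The simulator is the ground-truth generator for every downstream check, so
passing tests certify the *inference machinery* under the model's own
assumptions: binomial drift, Poisson depth, binomial counts, a correct and
complete diagnostic panel. Real data add mapping bias, contamination,
overdispersed coverage, panel errors and infection-rate dynamics, none of
which the generator emulates; results on real data inherit those caveats.

Two statistical points the test suite makes explicit:

- **Drift is process noise, not estimation error.** At `N = 75` the
  realized 15-generation trajectory of a selected clade scatters widely
  around the deterministic path (the implied per-replicate s has a spread
  of ~0.09; seed 42 of the worked example shows one replicate moving only
  0.27 → 0.31 under s = 0.18). The end-to-end recovery test therefore
  scores the estimation chain — Pool-Seq sampling, median estimation,
  inversion — against the s implied by the simulator's *realized*
  frequencies, where its error is ~0.01 at 50×, and separately checks that
  recovered values are centred on the generating s across 200 runs. No
  estimator can recover the generating s from a single finite-`N`
  trajectory more tightly than drift allows.
- **The calibration test bounds the false-positive rate, not power**: the
  statistic is conservative by construction (discreteness, tail doubling,
  unconditioned absorption).

Problem sizes in the default test run are chosen to keep the suite fast
while leaving Monte-Carlo error well inside the asserted tolerances: 2000
replicates for martingale/calibration checks, 10⁵ for the
distribution-vs-histogram comparison at `N = 20`, 200 seeded runs for the
end-to-end recovery and cumulative-frequency properties.

## Coverage-based infection calling

Both criteria strict: breadth > 0.95 of the *Wolbachia* genome covered ≥1×,
and *Wolbachia*/nuclear mean-depth ratio > 1. The call is monotone in both
inputs. Breadth is consumed as an input, not computed from alignments
(mapping is out of scope). Group summaries report mean and n−1 SD; size-1
groups report the mean with a missing SD. Display rounding is half away
from zero to 2 decimals. The packaged 12-fly fixture carries published
per-individual *Wolbachia* and nuclear depths; its per-sample mtDNA depths
and breadth values are synthetic stand-ins (never published per
individual), which is why the file is named
`base_population_coverage.synthetic.tsv`. No statistical test for titer
differences between environments is implemented — the source analyses
report significance without naming a statistic, and guessing one would
misattribute a method.

## Known limitations

- No host nuclear genetics; host-genotype effects on clade dynamics are out
  of scope.
- No estimation of `N` itself; it is an input from external evidence.
- No diffusion approximation; the dense-matrix exact test limits `N` to a
  few thousand.
- The uninfected founding pool's mtDNA composition is unmodelled, so mtDNA
  clade frequencies that include uninfected flies are only exact when the
  uninfected fraction is 0 or its clade composition is irrelevant to the
  question.
- The CI model is a deliberately simple hatch-rate penalty; no fecundity
  effects, no incomplete penetrance structure beyond the single intensity
  parameter.
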