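# Methods

## The problem and the model

At shotgun coverages of 0.04–0.1X, nearly every SNP that is covered at all
is covered by exactly one read. Diploid genotype calls are therefore
impossible for almost all loci, and kinship estimators that rely on
genotypes or genotype likelihoods behave erratically. The approach
implemented here makes the data regime explicit instead of fighting it:
every locus is reduced to a single allele ("forced homozygote"), and the
analysis is calibrated for the consequences.

**Forcing.** For a read pileup, one base with phred quality ≥ `min_qual`
(default 30, i.e. ≤0.1% error) is selected uniformly at random; sites with
no qualifying read are dropped and counted. For diploid input, one of the
two alleles is dropped uniformly at random. Forcing is idempotent —
a homozygous or already-forced call is returned deterministically and
consumes no randomness. The threshold is inclusive (≥ 30). Missing data are
never imputed, and a call whose allele is not one of the panel's two
alleles for that locus is excluded and counted, never recoded — silent
recoding would corrupt the frequency terms. No strand flipping is applied
anywhere; strand-ambiguous (A/T, C/G) SNPs are not filtered by default,
which is a documented risk when panel and data were typed on opposite
strands.

**Estimator.** The symmetric Queller–Goodnight coefficient is computed as a
ratio of sums across loci (see README for the per-locus terms), using
reference allele frequencies exactly as supplied by the `.frq` panel: no
within-sample re-estimation, no exclusion-of-focal-pair correction, no
small-sample bias correction, and no clamping — negative estimates are
reported as such. Loci whose combined denominator contribution is zero
(both individuals heterozygous at a biallelic locus, where
p_a + p_b = 1 makes the focal terms vanish) are uninformative; they are
skipped and counted, not treated as errors. A locus shared by a dyad is
used only if its panel frequency is strictly inside (0, 1).

On forced (single-allele) data the expected coefficient is the kinship
coefficient θ rather than the relatedness r = 2θ: one random allele per
individual per locus matches with probability θ + (1−θ)(p²+q²), which makes
the per-locus expected numerator 4θpq against an expected denominator 4pq.
Hence the halved class expectations 0.25 / 0.125 / 0 (first order / second
order / unrelated) versus the diploid 0.5 / 0.25 / 0.

## Calibration by simulation

Expectations and, more importantly, sampling spreads depend on the exact
set of shared loci and their frequencies, so each dyad is calibrated on its
own shared-SNP panel. For each class, `n_dyads` (default 2000) dyads are
simulated:

- **Unrelated** — two independent individuals drawn from Hardy–Weinberg
  proportions at the panel frequencies.
- **First order** — two offspring of the same two founders (full siblings).
  Parent–offspring pairs share the expectation 0.25 but have smaller
  variance (every locus shares exactly one allele by descent); a
  `first_order_parent_offspring` flag selects that variant.
- **Second order** — offspring of (P1, P2) and of (P1, P3): half siblings.

Pedigrees are simulated fully diploid and homozygosity is forced only on
the two scored dyad members. The obvious alternative — forcing founders
homozygous before breeding — would make offspring of a forced parent
inherit the same allele at every locus, inflating apparent sharing; a
`force_parents` flag exists so the variant can be examined, but it is not
the default and not used anywhere in the calibration. Loci are simulated
independently (no linkage), appropriate for a sparse genome-wide panel of a
few thousand SNPs; linkage disequilibrium between panel SNPs would make the
fitted sigmas slightly optimistic for dense local panels.

Each class sample is summarized by a maximum-likelihood normal fit
(mean, SD with divisor n — indistinguishable from the unbiased divisor at
n = 2000). The SD is clamped below at `sigma_floor = 1e-6` so degenerate
samples still yield a usable density. Simulated distributions are close to
normal at ≥1000 loci; the fit is used only as a scoring density, not as a
claim about tails.

## Trio hypothesis test

For three individuals A, B, C, each dyad gets an observed forced Rxy and
three fitted class densities on its own shared panel (3 classes × 3 dyads =
nine simulated data sets). A hypothesis assigns a named relationship
(Unrelated, Parent, Uncle, Full Sibling, Half Sibling) to each dyad; named
relationships map to classes (Parent, Full Sibling → first order; Uncle,
Half Sibling → second order) and are kept distinct even when
likelihood-equivalent, mirroring the conventional eleven-row hypothesis
set for a trio in which B and C may be siblings and A an outside relative.
The model log-likelihood is the sum over the three dyads of the log normal
density of the observed coefficient under the hypothesis's class for that
dyad; densities may exceed 1, so log-likelihoods may be positive.

Posteriors are the flat-prior softmax of the log-likelihoods, computed with
a log-sum-exp shift (posteriors are therefore exactly invariant to adding a
constant to all log-likelihoods). A flat prior reproduces the published
posterior table from its printed log-likelihoods to four significant
figures, which the test suite verifies arithmetically. Odds ratios between
hypothesis subsets are ratios of summed posteriors; a zero-posterior
denominator is reported as +inf with a flag rather than an exception.

## Synthetic data

The frequency generator emulates an ascertained common-SNP array: loci
`rs1..rsN` with minor-allele frequency uniform on (0.05, 0.5) by default —
a deliberate proxy for the MAF spectrum of genotyping-array panels after
rare-variant exclusion; real panels (e.g. a 1000 Genomes population `.frq`)
can be supplied instead at every entry point.

The trio fixture generator realizes a pedigree for a requested structure,
then emulates low-coverage sequencing by Bernoulli-thinning loci per
individual (`hit_prob`), with an optional fraction of two-read sites
(`depth2_prob`, default 0.02, matching the small >1X fraction seen in real
low-coverage data) and phred qualities drawn as rounded
normal(37, 3) clipped to [2, 41], so a realistic few percent of calls fall
under the phred-30 threshold. At these coverages a Poisson depth model
collapses to hit/no-hit almost everywhere, so Bernoulli thinning is the
model, not an approximation of one. What the generator does **not**
emulate: sequencing and post-mortem damage errors (no wrong bases are ever
written), reference bias, contamination, linkage, population structure or
inbreeding. Passing tests therefore demonstrate the statistical machinery
under clean conditions; on real ancient DNA, C→T/G→A damage and
contamination can bias individual calls in ways these fixtures do not
probe (a damage-aware transition-SNP filter is a natural extension and is
deliberately not applied by default).

## Randomness and reproducibility

All dataset-level operations draw from named substreams derived from a
single seed plus a stable key (locus id, class label), so results are
bit-reproducible and independent of iteration order, and any single site
or dyad can be replayed in isolation. Class distributions with equal seeds
are bit-identical across runs.

## Problem sizes

Calibration quantities are computed at 2000 dyads × 2000 loci; the trio
test simulates its nine distributions at 2000 dyads on panels of 1328,
1592 and 3480 loci (the shared-SNP counts of the motivating case study).
Unit and property tests use smaller panels (tens to hundreds of loci,
hundreds of dyads), sizes chosen so the whole suite runs in well under a
minute while keeping Monte-Carlo tolerances (4 standard errors) meaningful.

## Known limitations

- The normal fit understates tail mass slightly; posteriors very close to
  0 or 1 should be read as "overwhelming", not as calibrated tail
  probabilities.
- Frequencies are trusted as given; a mismatched reference population
  biases Rxy for all dyads in the same direction.
- The eleven-hypothesis set hard-codes the trio topology described above;
  other topologies (e.g. A parent of both B and C) need a custom
  hypothesis list, which `evaluate_trio` accepts.
- Inbreeding violates the θ = r/2 relationship assumed when reading forced
  coefficients against class expectations.
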