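# kinforce

Relatedness estimation from very low-coverage genomes by the
**forced-homozygote** approach: reduce every SNP to a single allele, estimate
the Queller–Goodnight pairwise coefficient against reference allele
frequencies, calibrate expectations by simulating related dyads, and resolve
trio relationship hypotheses by maximum likelihood.

## Who this is for

Ancient-DNA and forensic studies routinely produce shotgun data at 0.04–0.1X
coverage, where virtually every SNP is covered by a single read and
heterozygotes cannot be observed. Genotype-likelihood kinship tools need far
more data; mixing true heterozygous calls with possibly-false homozygous
ones corrupts the estimator. kinforce instead *forces* every locus
homozygous — one read (phred ≥ 30) is kept per site, or one allele is
dropped at random from a diploid call — and works with the halved
relatedness expectations this induces.

## The estimator

For individuals x = (a,b), y = (c,d) at locus *l* with reference allele
frequencies *p*, the symmetric Queller–Goodnight coefficient is a ratio of
sums over loci:

```
num_x = ½[I(a=c) + I(a=d) + I(b=c) + I(b=d)] − p_a − p_b
den_x = 1 + I(a=b) − p_a − p_b
Rxy   = Σ_l (num_x + num_y) / Σ_l (den_x + den_y)
```

Under forced homozygosity (a=b, c=d) this reduces per locus to
`(2·I(a=c) − p_a − p_c) / (2 − p_a − p_c)`. Because only half of each genome
is interrogated, expectations halve: first-order relatives (parent–offspring,
full siblings) drop from Rxy ≈ 0.5 to ≈ 0.25, second order (half siblings,
avuncular) from 0.25 to 0.125, unrelated stays at 0.

Observed coefficients are interpreted against **empirical distributions**:
for each dyad's shared-SNP panel, thousands of unrelated / half-sibling /
full-sibling dyads are simulated (Hardy–Weinberg founders, Mendelian
gene-dropping, then forcing) and a normal is fitted to each class. For a
trio, eleven relationship hypotheses (combinations of full sibling/parental
and half sibling/avuncular assignments) are scored by summed log normal
density and converted to flat-prior posterior probabilities.

## Worked example

Generate a synthetic low-coverage trio whose true structure is
(second order, second order, first order) — an individual A that is a half
sibling of full siblings B and C — and test it:

```
kinforce fixtures --kind frq  --n-loci 12000 --seed 9 --out panel.frq
kinforce fixtures --kind trio --n-loci 12000 --seed 9 --hit-prob 0.35 --out trio/
kinforce relate --pileup trio/A.pileup.tsv --pileup trio/B.pileup.tsv \
                --pileup trio/C.pileup.tsv --frq panel.frq --seed 3
```

which prints (shared loci per dyad land in the low thousands, as in real
0.04–0.1X data):

```
id_x  id_y  n_loci  rxy
A     B     1366    0.093297
A     C     1454    0.095472
B     C     1410    0.239847
```

A–B and A–C sit near the forced second-order expectation 0.125; B–C near
the forced first-order expectation 0.25. The hypothesis test

```
kinforce trio-test --pileup trio/A.pileup.tsv --pileup trio/B.pileup.tsv \
                   --pileup trio/C.pileup.tsv --frq panel.frq \
                   --seed 3 --n-dyads 400 --out report.json
```

reports `top hypothesis #4: (Uncle, Uncle, Full Sibling) posterior 0.999799`
— the true structure, recovered from ~1400 shared pseudo-haploid SNPs per
dyad.

`kinforce simulate --frq panel.frq --classes first,second,unrelated --plot
dist.png` writes the class distributions (JSON and histogram).

## File formats

- **.ped/.map** — text PLINK: six leading columns, two allele columns per
  mapped locus, `0` = missing.
- **.frq** — PLINK frequency table `CHR SNP A1 A2 MAF [NCHROBS]`; MAF is
  read as the frequency of A1.
- **pileup TSV** — three tab-separated columns per site: locus id,
  comma-joined base calls, comma-joined phred qualities.

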