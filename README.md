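# lodpaternity

Likelihood-ratio paternity inference for biallelic SNP genotypes, in the
CERVUS tradition, plus a pedigree simulator for validating assignments
against known ground truth.

Molecular ecologists routinely assign paternity in wild populations by
comparing, for each candidate male, the likelihood that he is the true
father of a focal offspring against the likelihood that the father is a
random draw from the population. This package implements that
likelihood-ratio engine for genotype matrices coded as alternate-allele
counts (0 = homozygous reference, 1 = heterozygous, 2 = homozygous
alternate, `NA` = missing), with both a known-mother (trio) mode and an
unknown-mother (pair) mode.

## The statistic

For offspring genotype $g_o$, known mother $g_m$, and candidate $g_f$ at
one locus with population reference-allele frequency $p$ (and $q = 1-p$):

$$\mathrm{LR} = \frac{P(g_o \mid g_m, g_f)}{P(g_o \mid g_m, \text{random male})}$$

The numerator follows Mendelian transmission (a homozygote transmits its
allele with probability 1, a heterozygote each allele with 1/2); the
denominator integrates the paternal allele over the population frequency,
which is identical to marginalizing the candidate over Hardy–Weinberg
genotype frequencies $p^2, 2pq, q^2$. With no known mother, the maternal
allele is integrated over the population too and the background is the
HWE frequency of $g_o$ itself. Loci are assumed unlinked, so the LOD
score of a candidate is the sum of the natural-log ratios over typed
loci:

$$\mathrm{LOD} = \sum_{\ell} \ln \mathrm{LR}_\ell$$

A Mendelian incompatibility makes the per-locus likelihood exactly zero;
to allow for genotyping error it is reassigned to a small floor
(default 0.01, user-configurable), so a single incompatible locus
penalizes a candidate heavily but does not exclude him outright. The
candidate with the highest LOD is the assigned father; ties are reported,
never silently broken.

## Worked example

Simulate a 30-individual population — 10 independent father–mother–
offspring trios typed at 99 unlinked biallelic loci — then ask for the
father of offspring `O3` given its known mother `M3`:

```sh
$ lodpaternity simulate --n-loci 99 --n-trios 10 --seed 42 --out-prefix amboseli
wrote 30 individuals x 99 loci to amboseli.genotypes.csv; 10 trios to amboseli.truth.csv (seed 42)

$ lodpaternity infer --genotypes amboseli.genotypes.csv --offspring O3 --mother M3 --out report.csv
top candidate: F3 (LOD = 20.6963, 99 loci used, 0 incompatible, 0 missing)
report written to report.csv

$ head -4 report.csv
candidate_id,lod,n_loci_used,n_compatible,n_incompatible,n_missing,rank,is_top
F3,20.696280655556848,99,99,0,0,1,True
O6,-32.733180112551935,99,88,11,0,2,False
F2,-33.17946721518036,99,87,12,0,3,False
```

The true father `F3` is compatible at every locus and his genotype fits
the offspring about $e^{20.7}$ times better than a random male's would;
every unrelated male carries a strongly negative LOD driven by his
Mendelian incompatibilities (11–12 loci at $\ln 0.02 \approx -3.9$ each
here). A full recovery experiment over all 10 trios:

```sh
$ lodpaternity recover --seed 42
recovered 10/10 true fathers (trio mode, seed 42)
  O1: top=F1 true=F1 margin=55.955 [ok ]
  ...
```

`margin` is the LOD gap between the best and second-best candidate. The
same machinery is available as a library (`lodpaternity.infer_paternity`,
`lodpaternity.recovery_experiment`, ...), and `--mother` can be omitted
for pair mode. Since the likelihood treats the two parents symmetrically,
maternity inference is the same call with the roles of the known parent
and the candidates swapped.

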