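# Methods

## Model

Each locus is biallelic with genotypes coded as alternate-allele counts
{0, 1, 2}. The reference-allele frequency at each locus, p, is estimated
by allele counting over *every* individual in the supplied matrix —
offspring and candidates included, with no leave-one-out correction:
p̂ = (2·n₀ + n₁) / (2·(n₀ + n₁ + n₂)) over non-missing genotypes. Some
parentage programs exclude focal individuals or apply small-sample
corrections; this implementation deliberately uses the full sample, which
is the simplest estimator and differs only at O(1/n).

Paternity is scored per candidate as a log likelihood ratio summed over
loci, assuming loci are unlinked and independent:

- **Trio mode** (mother known). Numerator: P(g_o | g_m, g_f) from
  Mendelian transmission probabilities (homozygote transmits its allele
  with probability 1, heterozygote with 1/2). Denominator: the same
  quantity with the paternal allele drawn at the population frequency —
  algebraically identical to marginalizing the candidate's genotype over
  Hardy–Weinberg frequencies (p², 2pq, q²), an identity the test suite
  checks exactly on a frequency grid.
- **Pair mode** (mother unknown). Numerator: P(g_o | g_f) with the
  maternal allele integrated over population frequencies. Denominator:
  the HWE frequency of g_o. The two modes are linked by an exact
  marginalization identity (integrating the mother over HWE in trio mode
  reproduces pair mode), also tested on a grid.

LOD scores are in **nats** (natural log). The base only rescales every
score by a constant, so rankings are base-invariant; natural log keeps
the arithmetic plain.

## Assumptions

Random mating (HWE background), unlinked loci, candidates unrelated to
the offspring under the null, and allele frequencies known rather than
estimated (their sampling error is ignored, as is conventional). No
assignment-confidence criterion is computed: the method reports raw LODs
and the top candidate, leaving Δ-LOD or simulation-based confidence to
the user.

## Error floor

A Mendelian incompatibility gives a per-locus likelihood of exactly 0,
which would veto a candidate on a single possible genotyping error. Any
zero **numerator** over a positive denominator is therefore reassigned to
a floor ε (default 0.01, validated > 0, settable per query), and the
locus is counted as *incompatible*. At a locus with p = 0.5 this costs
about ln 0.02 ≈ −3.9 nats, so a handful of incompatibilities still sinks
a candidate. The floor applies only to numerators that are exactly zero,
in both modes. A zero **denominator** means the offspring's genotype is
impossible regardless of the candidate — a mother–offspring Mendelian
conflict in trio mode, or a monomorphic background in pair mode. Such
loci implicate the input data, not the candidate, so they are *skipped*
for all candidates with a logged warning rather than floored.

## Locus accounting

Per candidate, each locus ends in exactly one state:

- `compatible` / `incompatible` — contributes its log-ratio to the LOD;
  `n_loci_used` is their sum,
- `missing` — offspring, candidate, or (trio mode) mother untyped;
  contributes nothing,
- `skipped` — monomorphic or all-missing in the population, or zero
  background as above; contributes nothing and is reported separately
  from `missing`.

The four counts always partition the locus set. LODs are summed with
`math.fsum`, so a candidate's score is exactly invariant to locus order.
Ties in the ranking share the better (competition) rank and set a `tie`
flag; output order is (LOD descending, candidate ID ascending), and tie
detection uses exact float equality — identical genotype rows produce
bit-identical sums, which is the case ties are meant to catch.

## Default candidate set

With sex labels present: every male except the focal offspring (the
mother is excluded by sex). Without labels: every individual except the
offspring and the named mother, with a warning that females may be
included.

## Simulator

The generator emulates a SNP-panel validation design: per-locus reference
frequencies drawn Uniform(freq_low, freq_high), founders at HWE,
offspring by Mendelian sampling of one allele per parent, then optional
noise. Defaults are **99 loci, 10 independent trios (30 individuals),
frequencies on [0.2, 0.8], zero error and missingness** — the frequency
band is bounded away from 0 and 1 so every locus is informative, and
trios share no parents. Offspring sexes are drawn at random, so male
offspring join other trios' candidate pools the way young males do in a
real sample. The noise model is the simplest one that exercises the
floor: each cell is independently masked with probability
`missing_rate`, else mistyped to one of the other two codes uniformly
with probability `error_rate`.

What the simulator does **not** emulate: linkage between loci, population
structure or hybrid ancestry, relatives among candidates (half-sibs,
grandfathers — the hard cases for real parentage analysis), genotype-
dependent error, and allele-frequency misestimation from small samples.
Perfect recovery on simulated data therefore shows the engine is correct,
not that any particular field data set will resolve paternity.

## Recovery experiment

For each simulated trio, trio-mode (or pair-mode) inference runs against
the default male candidate set; a trio counts as recovered only when the
top-LOD candidate is **unique** and equals the true father — ties count
as failures, the conservative choice. The reported margin is the LOD gap
to the runner-up. At the default design the true father is compatible at
all 99 loci while each unrelated male averages several incompatibilities
at ≈ −3.9 nats each, so margins run in the tens of nats and recovery is
10/10 across seeds.

## Numerical and testing choices

Probability kernels are exact rational arithmetic on floats (products of
0, 0.5, 1 and frequencies); identities are asserted to 1e-12. Monte-Carlo
checks use 10⁵ draws against 3-standard-error bands. Simulation-level
statistical tests are seeded and sized to keep the full suite under a
minute: 200 trios for the top-rank rate, 50 seeds × {5, 20, 99} loci for
the monotonicity of recovery in panel size, 30 seeds of a deliberately
noisy 12-locus design for the trio-versus-pair comparison. File I/O
round-trips are byte-exact (codes as bare integers, missing as `NA`).

## Limitations

Biallelic loci only (no microsatellites); no mistyping-rate likelihood
model beyond the zero-floor reassignment; no confidence levels on
assignments; single-offspring queries rather than joint pedigree
reconstruction.
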