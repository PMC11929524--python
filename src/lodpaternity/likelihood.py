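"""Exact Mendelian and Hardy-Weinberg probabilities for biallelic loci.

The paternity likelihood ratio at one locus compares two hypotheses for
an offspring genotype: the candidate male is the father, versus the
father is a random draw from the population.  In trio mode the mother's
genotype is known and conditioned on; in pair mode the maternal allele is
integrated over the population allele frequencies (Hardy-Weinberg
background).  A per-locus likelihood of exactly zero — a Mendelian
incompatibility — is reassigned to a small floor (default 0.01) so that a
single possible genotyping error penalizes but does not categorically
exclude a candidate.

Genotype codes count alternate alleles: 0, 1, 2.  Alleles are represented
as 0 (reference) and 1 (alternate), so an offspring genotype is the sum of
the maternal and paternal transmitted alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

REF, ALT = 0, 1
DEFAULT_FLOOR = 0.01


class LocusStatus(str, Enum):
    COMPATIBLE = "compatible"
    INCOMPATIBLE = "incompatible"
    MISSING = "missing"
    SKIPPED = "skipped"


@dataclass(frozen=True)
class LocusEvaluation:
    """Per-locus likelihood pieces for one candidate.

    ``numerator`` is post-floor; for an incompatible locus the pre-floor
    numerator was exactly 0 and ``numerator`` equals the configured floor.
    ``log_ratio`` is ln(numerator/denominator) and is 0 for loci with
    status ``missing`` or ``skipped`` (they do not enter the LOD sum).
    """

    locus_id: str
    status: LocusStatus
    numerator: float | None = None
    denominator: float | None = None
    log_ratio: float = 0.0


def transmission_prob(g_parent: int, allele: int) -> float:
    """Probability a parent of genotype ``g_parent`` transmits ``allele``.

    Mendelian segregation for a biallelic locus: a homozygote transmits
    its allele with certainty, a heterozygote transmits each with 1/2.
    """
    if g_parent not in (0, 1, 2):
        raise ValueError(f"invalid parent genotype code: {g_parent!r}")
    p_alt = g_parent / 2.0
    return p_alt if allele == ALT else 1.0 - p_alt


def offspring_prob_given_parents(g_o: int, g_m: int, g_f: int) -> float:
    """P(offspring genotype | both parental genotypes) under Mendel.

    Sums transmission probabilities over the four ordered allele pairs
    whose alternate-allele counts add to ``g_o``.
    """
    total = 0.0
    for a_m in (REF, ALT):
        for a_p in (REF, ALT):
            if a_m + a_p == g_o:
                total += transmission_prob(g_m, a_m) * transmission_prob(g_f, a_p)
    return total


def hwe_genotype_prob(g: int, p_ref: float) -> float:
    """Hardy-Weinberg genotype frequency: p^2, 2pq, q^2 for g = 0, 1, 2."""
    q = 1.0 - p_ref
    if g == 0:
        return p_ref * p_ref
    if g == 1:
        return 2.0 * p_ref * q
    if g == 2:
        return q * q
    raise ValueError(f"invalid genotype code: {g!r}")


def offspring_prob_given_single_parent(g_o: int, g_f: int, p_ref: float) -> float:
    """P(offspring genotype | one parent), other parent's allele from HWE.

    The known parent transmits under Mendelian rules; the unknown parent
    contributes a reference allele with probability ``p_ref``.
    """
    total = 0.0
    for a_p in (REF, ALT):
        for a_m in (REF, ALT):
            if a_m + a_p == g_o:
                freq_m = p_ref if a_m == REF else 1.0 - p_ref
                total += transmission_prob(g_f, a_p) * freq_m
    return total


def _random_father_background(g_o: int, g_m: int, p_ref: float) -> float:
    """Trio-mode denominator: known mother, paternal allele drawn at the
    population frequency.  Equals the HWE-marginalized trio numerator."""
    total = 0.0
    for a_p in (REF, ALT):
        freq_p = p_ref if a_p == REF else 1.0 - p_ref
        for a_m in (REF, ALT):
            if a_m + a_p == g_o:
                total += freq_p * transmission_prob(g_m, a_m)
    return total


def locus_log_ratio(
    g_o: int | None,
    g_m: int | None,
    g_f: int | None,
    p_ref: float,
    floor: float = DEFAULT_FLOOR,
    locus_id: str = "",
    mother_known: bool = True,
) -> LocusEvaluation:
    """Evaluate one locus for one candidate father.

    Trio mode (``mother_known``): numerator = P(g_o | g_m, g_f), denominator
    = P(g_o | g_m, random father).  Pair mode: numerator = P(g_o | g_f,
    random mother), denominator = HWE P(g_o).  Missing offspring, candidate,
    or (in trio mode) mother genotype gives status ``missing``.  A zero
    denominator — the locus is impossible regardless of the candidate, e.g.
    a mother-offspring Mendelian conflict — gives status ``skipped``.  A
    zero numerator over a positive denominator is reassigned to ``floor``
    and marked ``incompatible``.
    """
    if floor <= 0:
        raise ValueError(f"error floor must be > 0, got {floor!r}")
    if g_o is None or g_f is None or (mother_known and g_m is None):
        return LocusEvaluation(locus_id=locus_id, status=LocusStatus.MISSING)

    if mother_known:
        numerator = offspring_prob_given_parents(g_o, g_m, g_f)
        denominator = _random_father_background(g_o, g_m, p_ref)
    else:
        numerator = offspring_prob_given_single_parent(g_o, g_f, p_ref)
        denominator = hwe_genotype_prob(g_o, p_ref)

    if denominator == 0.0:
        return LocusEvaluation(locus_id=locus_id, status=LocusStatus.SKIPPED)

    if numerator == 0.0:
        numerator = floor
        status = LocusStatus.INCOMPATIBLE
    else:
        status = LocusStatus.COMPATIBLE
    return LocusEvaluation(
        locus_id=locus_id,
        status=status,
        numerator=numerator,
        denominator=denominator,
        log_ratio=math.log(numerator / denominator),
    )
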