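"""Candidate-father scoring: LOD aggregation, ranking, and reporting.

Each candidate male is scored against a focal offspring (and, when known,
its mother) by summing per-locus log likelihood ratios over all informative
loci; the candidate with the highest LOD is the assigned father.  Ties are
reported, never silently broken.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencyTable, GenotypeMatrix, compute_allele_frequencies
from .likelihood import DEFAULT_FLOOR, LocusEvaluation, LocusStatus, locus_log_ratio

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PaternityQuery:
    """One offspring, an optional known mother, and the candidate set."""

    offspring_id: str
    candidate_ids: tuple[str, ...]
    mother_id: str | None = None
    floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError(f"error floor must be > 0, got {self.floor!r}")
        if not self.candidate_ids:
            raise ValueError("candidate set is empty")
        if self.offspring_id in self.candidate_ids:
            raise ValueError(
                f"offspring {self.offspring_id!r} cannot be its own candidate"
            )
        if self.mother_id is not None and self.mother_id in self.candidate_ids:
            raise ValueError(
                f"mother {self.mother_id!r} cannot be a candidate father"
            )

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        known = set(matrix.individual_ids)
        for label, ids in (
            ("offspring", [self.offspring_id]),
            ("mother", [self.mother_id] if self.mother_id else []),
            ("candidate", self.candidate_ids),
        ):
            for ind in ids:
                if ind not in known:
                    raise KeyError(f"unknown {label} ID: {ind!r}")


@dataclass
class CandidateResult:
    """One candidate's LOD score and per-status locus counts.

    ``n_loci_used`` counts the loci that actually contribute to the LOD
    sum (compatible + incompatible); ``n_missing`` counts loci where the
    offspring's, mother's, or candidate's genotype is untyped; ``n_skipped``
    counts loci that are uninformative for every candidate (monomorphic, or
    a mother-offspring Mendelian conflict in trio mode).
    """

    candidate_id: str
    lod: float
    n_compatible: int
    n_incompatible: int
    n_missing: int
    n_skipped: int
    rank: int = 0
    is_top: bool = False
    evaluations: list[LocusEvaluation] = field(default_factory=list, repr=False)

    @property
    def n_loci_used(self) -> int:
        return self.n_compatible + self.n_incompatible


@dataclass
class PaternityReport:
    """Ranked candidate results for one query.

    ``results`` are sorted by LOD descending, ties broken by candidate ID
    ascending; ``top_candidate_ids`` lists every candidate sharing the
    maximal LOD and ``tie`` flags whether there is more than one.
    """

    query: PaternityQuery
    results: list[CandidateResult]
    top_candidate_ids: tuple[str, ...]
    tie: bool

    @property
    def top_candidate_id(self) -> str:
        return self.top_candidate_ids[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "candidate_id": [r.candidate_id for r in self.results],
                "lod": [r.lod for r in self.results],
                "n_loci_used": [r.n_loci_used for r in self.results],
                "n_compatible": [r.n_compatible for r in self.results],
                "n_incompatible": [r.n_incompatible for r in self.results],
                "n_missing": [r.n_missing for r in self.results],
                "rank": [r.rank for r in self.results],
                "is_top": [r.is_top for r in self.results],
            }
        )


def write_report(report: PaternityReport, path) -> None:
    """Serialize a report as delimited text, one row per ranked candidate."""
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    frame = report.to_frame()
    if frame.empty:
        logger.warning("writing a report with no candidates: %s", path)
    frame.to_csv(path, sep=sep, index=False)


def score_candidate(
    matrix: GenotypeMatrix,
    freqs: AlleleFrequencyTable,
    offspring_id: str,
    candidate_id: str,
    mother_id: str | None = None,
    floor: float = DEFAULT_FLOOR,
) -> CandidateResult:
    """Score one candidate father across all loci.

    Monomorphic loci are skipped; the remaining loci are evaluated with
    :func:`locus_log_ratio` in trio mode when ``mother_id`` is given, else
    pair mode.  The LOD is the sum of log ratios over compatible and
    incompatible loci, treating loci as independent.
    """
    g_o = matrix.row(offspring_id)
    g_f = matrix.row(candidate_id)
    g_m = matrix.row(mother_id) if mother_id is not None else None
    mother_known = mother_id is not None
    p_ref = freqs.p_ref_array
    mono = freqs.monomorphic_array

    evals: list[LocusEvaluation] = []
    counts = {status: 0 for status in LocusStatus}
    for j, locus in enumerate(matrix.locus_ids):
        if mono[j]:
            ev = LocusEvaluation(locus_id=locus, status=LocusStatus.SKIPPED)
        else:
            ev = locus_log_ratio(
                g_o=None if math.isnan(g_o[j]) else int(g_o[j]),
                g_m=(
                    None
                    if g_m is None or math.isnan(g_m[j])
                    else int(g_m[j])
                ),
                g_f=None if math.isnan(g_f[j]) else int(g_f[j]),
                p_ref=p_ref[j],
                floor=floor,
                locus_id=locus,
                mother_known=mother_known,
            )
        counts[ev.status] += 1
        evals.append(ev)

    # fsum: correctly rounded, so the LOD is invariant to locus order
    return CandidateResult(
        candidate_id=candidate_id,
        lod=math.fsum(ev.log_ratio for ev in evals),
        n_compatible=counts[LocusStatus.COMPATIBLE],
        n_incompatible=counts[LocusStatus.INCOMPATIBLE],
        n_missing=counts[LocusStatus.MISSING],
        n_skipped=counts[LocusStatus.SKIPPED],
        evaluations=evals,
    )


def infer_paternity(
    matrix: GenotypeMatrix,
    query: PaternityQuery,
    freqs: AlleleFrequencyTable | None = None,
) -> PaternityReport:
    """Score every candidate in the query and rank them by LOD.

    Allele frequencies are estimated from the full matrix unless supplied.
    Ranks use competition ranking (tied LODs share the smaller rank); all
    candidates attaining the maximal LOD are flagged top.
    """
    query.validate_against(matrix)
    if matrix.n_loci > 0 and bool(matrix.genotypes.loc[query.offspring_id].isna().all()):
        raise ValueError(
            f"offspring {query.offspring_id!r} has no typed genotypes"
        )
    if freqs is None:
        freqs = compute_allele_frequencies(matrix)

    results = [
        score_candidate(
            matrix,
            freqs,
            offspring_id=query.offspring_id,
            candidate_id=cid,
            mother_id=query.mother_id,
            floor=query.floor,
        )
        for cid in query.candidate_ids
    ]
    results.sort(key=lambda r: (-r.lod, r.candidate_id))

    lods = np.array([r.lod for r in results])
    for i, r in enumerate(results):
        r.rank = 1 + int(np.sum(lods > r.lod))
    max_lod = results[0].lod
    top = tuple(r.candidate_id for r in results if r.lod == max_lod)
    for r in results:
        r.is_top = r.candidate_id in top

    if results and results[0].n_skipped:
        logger.warning(
            "%d loci skipped (monomorphic or mother-offspring conflict) for "
            "offspring %s",
            results[0].n_skipped,
            query.offspring_id,
        )
    return PaternityReport(
        query=query, results=results, top_candidate_ids=top, tie=len(top) > 1
    )


def default_candidate_set(
    matrix: GenotypeMatrix,
    offspring_id: str,
    mother_id: str | None = None,
) -> tuple[str, ...]:
    """The default candidate pool: every male other than the offspring.

    When the matrix carries no sex labels, falls back to all individuals
    except the offspring and (if given) the mother, with a warning that
    females may be included.
    """
    if offspring_id not in matrix.individual_ids:
        raise KeyError(f"unknown offspring ID: {offspring_id!r}")
    if matrix.sex is not None:
        candidates = tuple(m for m in matrix.males() if m != offspring_id)
    else:
        logger.warning(
            "no sex labels in the genotype matrix; using all individuals "
            "except the offspring%s as candidates",
            " and mother" if mother_id else "",
        )
        excluded = {offspring_id, mother_id}
        candidates = tuple(i for i in matrix.individual_ids if i not in excluded)
    if not candidates:
        raise ValueError("default candidate set is empty")
    return candidates
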