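"""Pedigree simulator: synthetic populations with known father-mother-offspring
trios for paternity-recovery experiments.

Founders are drawn at Hardy-Weinberg equilibrium from per-locus reference
allele frequencies sampled uniformly on a configurable band (default 0.2 to
0.8, so every locus is informative); offspring receive one Mendelian allele
from each parent.  Optional noise mistypes a genotype to a uniformly chosen
different code, or masks it as missing.  Every dataset is reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, compute_allele_frequencies
from .inference import PaternityQuery, default_candidate_set, infer_paternity
from .likelihood import DEFAULT_FLOOR


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic population.

    Defaults mirror a SNP-panel validation design: 99 unlinked biallelic
    loci across 10 independent trios (30 individuals), error-free.
    """

    n_loci: int = 99
    n_trios: int = 10
    freq_low: float = 0.2
    freq_high: float = 0.8
    n_extra_males: int = 0
    n_extra_females: int = 0
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.freq_low <= self.freq_high < 1.0):
            raise ValueError(
                f"frequency bounds must satisfy 0 < low <= high < 1, got "
                f"({self.freq_low}, {self.freq_high})"
            )
        for name in ("error_rate", "missing_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {rate!r}")
        for name in ("n_loci", "n_trios", "n_extra_males", "n_extra_females"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TrioRecord:
    offspring_id: str
    mother_id: str
    father_id: str


@dataclass
class SimulatedDataset:
    """A genotype matrix plus the pedigree truth it was generated from."""

    matrix: GenotypeMatrix
    truth: tuple[TrioRecord, ...]
    config: SimulationConfig
    p_ref_true: np.ndarray = field(repr=False, default=None)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offspring_id": [t.offspring_id for t in self.truth],
                "mother_id": [t.mother_id for t in self.truth],
                "father_id": [t.father_id for t in self.truth],
            }
        )


def sample_founder_genotype(p_ref: float, rng: np.random.Generator) -> int:
    """Draw one founder genotype at HWE: alt-allele count ~ Binomial(2, q)."""
    if not (0.0 < p_ref < 1.0):
        raise ValueError(f"p_ref must be in (0, 1), got {p_ref!r}")
    return int(rng.binomial(2, 1.0 - p_ref))


def sample_offspring_genotype(
    g_m: int, g_f: int, rng: np.random.Generator
) -> int:
    """Draw one Mendelian offspring genotype from two parental codes."""
    a_m = rng.binomial(1, g_m / 2.0)
    a_p = rng.binomial(1, g_f / 2.0)
    return int(a_m + a_p)


def apply_noise(
    matrix: GenotypeMatrix,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Independently per cell: mask as missing with ``missing_rate``, else
    mistype to a uniformly chosen different code with ``error_rate``."""
    vals = matrix.genotypes.to_numpy(dtype="float64", na_value=np.nan)
    shape = vals.shape
    miss = rng.random(shape) < missing_rate
    err = rng.random(shape) < error_rate
    # uniformly one of the two other codes: shift by 1 or 2 mod 3
    shift = rng.integers(1, 3, size=shape)
    mistyped = np.mod(vals + shift, 3.0)
    out = np.where(err & ~np.isnan(vals), mistyped, vals)
    out = np.where(miss, np.nan, out)
    frame = pd.DataFrame(
        out, index=matrix.genotypes.index, columns=matrix.genotypes.columns
    ).astype("Int8")
    return GenotypeMatrix(genotypes=frame, sex=matrix.sex)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one synthetic population with known pedigree truth.

    Individuals are, in order: per trio a father ``F{i}``, mother ``M{i}``,
    and offspring ``O{i}`` (offspring sex drawn at random), then any extra
    unrelated males ``XM{i}`` and females ``XF{i}``.  Deterministic given
    the config seed.
    """
    rng = np.random.default_rng(config.seed)
    p_ref = rng.uniform(config.freq_low, config.freq_high, size=config.n_loci)

    ids: list[str] = []
    sexes: list[str] = []
    rows: list[np.ndarray] = []
    truth: list[TrioRecord] = []

    def founder_row() -> np.ndarray:
        return rng.binomial(2, 1.0 - p_ref).astype(float)

    for i in range(1, config.n_trios + 1):
        g_f = founder_row()
        g_m = founder_row()
        a_m = rng.binomial(1, g_m / 2.0)
        a_p = rng.binomial(1, g_f / 2.0)
        g_o = (a_m + a_p).astype(float)
        off_sex = "male" if rng.random() < 0.5 else "female"
        ids += [f"F{i}", f"M{i}", f"O{i}"]
        sexes += ["male", "female", off_sex]
        rows += [g_f, g_m, g_o]
        truth.append(TrioRecord(f"O{i}", f"M{i}", f"F{i}"))

    for i in range(1, config.n_extra_males + 1):
        ids.append(f"XM{i}")
        sexes.append("male")
        rows.append(founder_row())
    for i in range(1, config.n_extra_females + 1):
        ids.append(f"XF{i}")
        sexes.append("female")
        rows.append(founder_row())

    locus_ids = [f"L{j}" for j in range(1, config.n_loci + 1)]
    genotypes = pd.DataFrame(
        np.array(rows).reshape(len(ids), config.n_loci),
        index=pd.Index(ids, name="id"),
        columns=locus_ids,
    ).astype("Int8")
    sex = pd.Series(sexes, index=genotypes.index, name="sex")
    matrix = GenotypeMatrix(genotypes=genotypes, sex=sex)

    if config.error_rate > 0 or config.missing_rate > 0:
        matrix = apply_noise(matrix, config.error_rate, config.missing_rate, rng)

    return SimulatedDataset(
        matrix=matrix, truth=tuple(truth), config=config, p_ref_true=p_ref
    )


@dataclass
class TrioOutcome:
    offspring_id: str
    true_father_id: str
    top_candidate_ids: tuple[str, ...]
    correct: bool
    lod_margin: float


@dataclass
class RecoverySummary:
    """Outcome of a paternity-recovery experiment over simulated trios.

    ``n_correct`` counts trios whose *unique* top-LOD candidate is the true
    father; ties count as failures.  ``lod_margin`` is the LOD gap between
    the best and second-best candidate (0 under a tie, NaN with a single
    candidate).
    """

    config: SimulationConfig
    mode: str
    floor: float
    n_correct: int
    n_trios: int
    outcomes: tuple[TrioOutcome, ...]

    @property
    def recovery_rate(self) -> float:
        return self.n_correct / self.n_trios if self.n_trios else float("nan")


def recovery_experiment(
    config: SimulationConfig,
    mode: str = "trio",
    floor: float = DEFAULT_FLOOR,
) -> RecoverySummary:
    """Simulate a dataset and test whether each trio's true father is the
    unique top-LOD candidate among all other males.

    ``mode='trio'`` conditions on the known mother; ``mode='pair'`` ignores
    her genotype in scoring (she is still excluded from the candidate set
    by sex).
    """
    if mode not in ("trio", "pair"):
        raise ValueError(f"mode must be 'trio' or 'pair', got {mode!r}")
    if config.n_trios < 1:
        raise ValueError("recovery experiment needs at least one trio")

    dataset = simulate_dataset(config)
    matrix = dataset.matrix
    freqs = compute_allele_frequencies(matrix)

    outcomes: list[TrioOutcome] = []
    for trio in dataset.truth:
        candidates = default_candidate_set(matrix, trio.offspring_id)
        query = PaternityQuery(
            offspring_id=trio.offspring_id,
            mother_id=trio.mother_id if mode == "trio" else None,
            candidate_ids=candidates,
            floor=floor,
        )
        report = infer_paternity(matrix, query, freqs=freqs)
        correct = (not report.tie) and report.top_candidate_id == trio.father_id
        if len(report.results) > 1:
            margin = report.results[0].lod - report.results[1].lod
        else:
            margin = float("nan")
        outcomes.append(
            TrioOutcome(
                offspring_id=trio.offspring_id,
                true_father_id=trio.father_id,
                top_candidate_ids=report.top_candidate_ids,
                correct=correct,
                lod_margin=margin,
            )
        )

    return RecoverySummary(
        config=config,
        mode=mode,
        floor=floor,
        n_correct=sum(o.correct for o in outcomes),
        n_trios=config.n_trios,
        outcomes=tuple(outcomes),
    )


def config_with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
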