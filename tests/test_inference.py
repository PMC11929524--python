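"""Candidate scoring, LOD aggregation, ranking, and report output."""

import math

import numpy as np
import pytest

from lodpaternity import (
    PaternityQuery,
    SimulationConfig,
    compute_allele_frequencies,
    default_candidate_set,
    infer_paternity,
    read_genotype_matrix,
    score_candidate,
    simulate_dataset,
    write_report,
)

from conftest import make_matrix


def uniform_half_matrix(rows, loci):
    """Matrix padded so every locus has p_ref exactly 0.5."""
    return make_matrix(rows, loci)


class TestScoreCandidate:
    def test_two_locus_toy_lod(self):
        # locus A: m=0,o=1,f=2 -> ln 2; locus B: m=0,o=0,f=2 -> ln 0.02
        # (individuals chosen so both loci have p_ref = 0.5)
        m = make_matrix(
            {
                "M": [0, 0],
                "O": [1, 0],
                "F": [2, 2],
                "P1": [2, 2],
                "P2": [0, 0],
                "P3": [2, 2],
                "P4": [0, 1],
            },
            ["A", "B"],
        )
        freqs = compute_allele_frequencies(m)
        assert freqs.p_ref("A") == 0.5 and freqs.p_ref("B") == 0.5
        r = score_candidate(m, freqs, "O", "F", mother_id="M", floor=0.01)
        assert r.lod == pytest.approx(math.log(2) + math.log(0.02), abs=1e-12)
        assert (r.n_compatible, r.n_incompatible) == (1, 1)
        assert r.n_loci_used == 2

    def test_status_counts_partition_all_loci(self, toy_matrix):
        freqs = compute_allele_frequencies(toy_matrix)
        r = score_candidate(toy_matrix, freqs, "O1", "F2", mother_id="M1")
        assert (
            r.n_compatible + r.n_incompatible + r.n_missing + r.n_skipped
            == toy_matrix.n_loci
        )

    def test_identical_genotypes_identical_lod(self, rng):
        ds = simulate_dataset(SimulationConfig(n_trios=2, n_loci=40, seed=5))
        m = ds.matrix
        clone = m.genotypes.copy()
        clone.loc["F2"] = clone.loc["F1"]
        m2 = type(m)(genotypes=clone, sex=m.sex)
        freqs = compute_allele_frequencies(m2)
        r1 = score_candidate(m2, freqs, "O1", "F1", mother_id="M1")
        r2 = score_candidate(m2, freqs, "O1", "F2", mother_id="M1")
        assert r1.lod == r2.lod

    def test_true_father_clean_trio_has_no_incompatible_loci(self):
        ds = simulate_dataset(SimulationConfig(seed=11))
        freqs = compute_allele_frequencies(ds.matrix)
        for trio in ds.truth:
            r = score_candidate(
                ds.matrix, freqs, trio.offspring_id, trio.father_id,
                mother_id=trio.mother_id,
            )
            assert r.n_incompatible == 0
            assert r.n_missing == 0

    def test_unknown_id_rejected(self, toy_matrix):
        freqs = compute_allele_frequencies(toy_matrix)
        with pytest.raises(KeyError, match="GHOST"):
            score_candidate(toy_matrix, freqs, "O1", "GHOST", mother_id="M1")


class TestInferPaternity:
    def test_ranking_and_top(self, toy_matrix):
        report = infer_paternity(
            toy_matrix,
            PaternityQuery("O1", ("F1", "F2"), mother_id="M1"),
        )
        assert [r.candidate_id for r in report.results] == ["F1", "F2"]
        assert report.top_candidate_ids == ("F1",)
        assert not report.tie
        assert report.results[0].rank == 1
        assert report.results[1].rank == 2

    def test_single_candidate_is_top_even_if_negative(self, toy_matrix):
        report = infer_paternity(
            toy_matrix, PaternityQuery("O1", ("F2",), mother_id="M1")
        )
        assert report.results[0].is_top
        assert report.results[0].lod < 0

    def test_identical_rows_tie_at_rank_one(self):
        m = make_matrix(
            {"M": [0, 1], "O": [1, 1], "A": [2, 1], "B": [2, 1], "C": [0, 0]},
            ["L1", "L2"],
        )
        report = infer_paternity(m, PaternityQuery("O", ("A", "B", "C"), "M"))
        assert report.tie
        assert report.top_candidate_ids == ("A", "B")
        assert [r.rank for r in report.results] == [1, 1, 3]

    def test_locus_order_permutation_invariant(self):
        ds = simulate_dataset(SimulationConfig(n_trios=3, n_loci=30, seed=7))
        m = ds.matrix
        rng = np.random.default_rng(0)
        shuffled = m.genotypes[list(rng.permutation(m.locus_ids))]
        m2 = type(m)(genotypes=shuffled, sex=m.sex)
        q = PaternityQuery("O1", ("F1", "F2", "F3"), mother_id="M1")
        lods1 = {r.candidate_id: r.lod for r in infer_paternity(m, q).results}
        lods2 = {r.candidate_id: r.lod for r in infer_paternity(m2, q).results}
        assert lods1 == lods2

    def test_dropping_missing_locus_preserves_lod(self):
        m = make_matrix(
            {"M": [0, 1], "O": [1, 1], "F": [2, None], "X": [0, 1]},
            ["L1", "L2"],
        )
        q = PaternityQuery("O", ("F",), "M")
        full = infer_paternity(m, q).results[0]
        assert full.n_missing == 1
        m_drop = type(m)(genotypes=m.genotypes[["L1"]], sex=m.sex)
        dropped = infer_paternity(m_drop, q).results[0]
        assert full.lod == dropped.lod

    def test_offspring_cannot_be_candidate(self):
        with pytest.raises(ValueError, match="own candidate"):
            PaternityQuery("O", ("O", "F"), "M")

    def test_mother_cannot_be_candidate(self):
        with pytest.raises(ValueError, match="mother"):
            PaternityQuery("O", ("M", "F"), "M")

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PaternityQuery("O", ())

    def test_untyped_offspring_rejected(self):
        m = make_matrix({"O": [None, None], "F": [1, 1], "M": [0, 0]},
                        ["L1", "L2"])
        with pytest.raises(ValueError, match="no typed genotypes"):
            infer_paternity(m, PaternityQuery("O", ("F",), "M"))

    def test_true_father_top_among_twenty_candidates(self):
        ds = simulate_dataset(
            SimulationConfig(n_trios=1, n_extra_males=19, seed=3)
        )
        trio = ds.truth[0]
        report = infer_paternity(
            ds.matrix,
            PaternityQuery(
                trio.offspring_id,
                default_candidate_set(ds.matrix, trio.offspring_id),
                mother_id=trio.mother_id,
            ),
        )
        assert len(report.query.candidate_ids) >= 20
        assert report.top_candidate_ids == (trio.father_id,)


class TestStatisticalBehaviour:
    def test_true_father_recovered_and_unrelated_males_penalized(self):
        # >= 200 error-free trios; unrelated males should average a
        # negative per-locus log-ratio, true fathers should win nearly always
        n_correct = n_trios = 0
        unrelated_mean_lr = []
        for seed in range(20):
            ds = simulate_dataset(SimulationConfig(seed=100 + seed))
            freqs = compute_allele_frequencies(ds.matrix)
            for trio in ds.truth:
                cands = default_candidate_set(ds.matrix, trio.offspring_id)
                q = PaternityQuery(trio.offspring_id, cands, trio.mother_id)
                report = infer_paternity(ds.matrix, q, freqs=freqs)
                n_trios += 1
                n_correct += (
                    not report.tie
                    and report.top_candidate_id == trio.father_id
                )
                for r in report.results:
                    if r.candidate_id != trio.father_id and r.n_loci_used:
                        unrelated_mean_lr.append(r.lod / r.n_loci_used)
        assert n_trios >= 200
        assert n_correct / n_trios >= 0.99
        assert np.mean(unrelated_mean_lr) < 0

    def test_trio_mode_more_informative_than_pair_mode(self):
        # conditioning on the true mother should raise the true father's
        # mean LOD relative to pair mode on identical data
        trio_lods, pair_lods = [], []
        for seed in range(12):
            ds = simulate_dataset(SimulationConfig(n_trios=4, seed=200 + seed))
            freqs = compute_allele_frequencies(ds.matrix)
            for t in ds.truth:
                trio_lods.append(
                    score_candidate(ds.matrix, freqs, t.offspring_id,
                                    t.father_id, mother_id=t.mother_id).lod
                )
                pair_lods.append(
                    score_candidate(ds.matrix, freqs, t.offspring_id,
                                    t.father_id, mother_id=None).lod
                )
        assert np.mean(trio_lods) >= np.mean(pair_lods)


class TestDefaultCandidateSet:
    def test_males_minus_offspring(self):
        ds = simulate_dataset(SimulationConfig(n_trios=2, n_loci=5, seed=1))
        cands = default_candidate_set(ds.matrix, "O1")
        assert "O1" not in cands
        assert set(cands) <= set(ds.matrix.males())
        assert {"F1", "F2"} <= set(cands)

    def test_no_sex_labels_excludes_mother_with_warning(self, caplog):
        m = make_matrix(
            {f"I{k}": [0, 1] for k in range(10)}, ["L1", "L2"]
        )
        with caplog.at_level("WARNING"):
            cands = default_candidate_set(m, "I0", mother_id="I1")
        assert len(cands) == 8
        assert "sex" in caplog.text

    def test_empty_set_is_error(self):
        m = make_matrix(
            {"A": [0], "B": [1]}, ["L1"],
            sex={"A": "female", "B": "female"},
        )
        with pytest.raises(ValueError, match="empty"):
            default_candidate_set(m, "A")


class TestWriteReport:
    def test_report_file_columns_and_order(self, toy_matrix, tmp_path):
        report = infer_paternity(
            toy_matrix, PaternityQuery("O1", ("F1", "F2"), "M1")
        )
        out = tmp_path / "report.csv"
        write_report(report, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == (
            "candidate_id,lod,n_loci_used,n_compatible,n_incompatible,"
            "n_missing,rank,is_top"
        )
        assert len(lines) == 3
        assert lines[1].startswith("F1,")

    def test_round_trip_through_file(self, toy_matrix, tmp_path):
        import pandas as pd

        report = infer_paternity(
            toy_matrix, PaternityQuery("O1", ("F1", "F2"), "M1")
        )
        out = tmp_path / "report.tsv"
        write_report(report, out)
        frame = pd.read_csv(out, sep="\t")
        assert list(frame["rank"]) == [1, 2]
        assert bool(frame["is_top"][0])
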