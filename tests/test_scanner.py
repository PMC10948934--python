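"""Window scoring, proteome scanning, best-hit selection, significance."""

import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_matrix, oracle_scan, oracle_score
from vap_triage.matrices import (
    AMINO_ACIDS,
    MotifClass,
    UnknownResiduePolicy,
    ideal_sequence,
)
from vap_triage.scanner import (
    best_hits,
    classify_significant,
    hits_to_table,
    scan_proteome,
    scan_sequence,
    score_window,
)
from vap_triage.simulate import gen_proteome, random_matrix

AA = "".join(AMINO_ACIDS)


def random_seq(rng, n):
    return "".join(rng.choice(list(AA), size=n))


class TestScoreWindow:
    def test_ideal_sequence_scores_exactly_zero(self, conventional_matrix):
        assert score_window(
            ideal_sequence(conventional_matrix), conventional_matrix
        ) == 0.0

    def test_serine_at_c4_costs_four_under_conventional(
        self, conventional_matrix
    ):
        ideal = ideal_sequence(conventional_matrix)
        window = ideal[:9] + "S" + ideal[10:]  # C4 is window position 10
        assert score_window(window, conventional_matrix) == 4.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_cell_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng)
        w = random_seq(rng, 19)
        assert score_window(w, m) == oracle_score(w, m)

    def test_wrong_length_and_non_letters_rejected(self, conventional_matrix):
        with pytest.raises(ValueError, match="19"):
            score_window("ACD", conventional_matrix)
        with pytest.raises(ValueError, match="non-letter"):
            score_window("ACDEFGHIKLMNPQRS*VW", conventional_matrix)

    def test_unknown_residue_charged_column_max(self, conventional_matrix):
        ideal = ideal_sequence(conventional_matrix)
        window = "X" + ideal[1:]
        expected = float(conventional_matrix.table["U1"].max())
        assert score_window(window, conventional_matrix) == expected


class TestScanSequence:
    def test_length_19_yields_single_window_at_start_1(
        self, conventional_matrix
    ):
        hits = scan_sequence("A" * 19, conventional_matrix)
        assert len(hits) == 1 and hits[0].start == 1
        assert hits[0].core_start == 7

    def test_length_25_yields_seven_windows(self, conventional_matrix):
        hits = scan_sequence("A" * 25, conventional_matrix)
        assert [h.start for h in hits] == list(range(1, 8))

    def test_short_sequence_warns_and_returns_empty(
        self, conventional_matrix, caplog
    ):
        with caplog.at_level(logging.WARNING):
            hits = scan_sequence("ACDEF", conventional_matrix)
        assert hits == []
        assert "no windows scored" in caplog.text

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng)
        seq = random_seq(rng, 200)
        hits = scan_sequence(seq, m)
        assert [(h.start, h.score) for h in hits] == oracle_scan(seq, m)

    def test_skip_window_policy_drops_windows_with_unknowns(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng)
        m = type(m)(
            name=m.name,
            motif_class=m.motif_class,
            table=m.table,
            unknown_residue_policy=UnknownResiduePolicy.SKIP_WINDOW,
        )
        seq = random_seq(rng, 40)
        seq = seq[:20] + "X" + seq[21:]
        hits = scan_sequence(seq, m)
        # windows covering position 21 (1-based) are dropped
        dropped = {s for s in range(1, 40 - 19 + 2) if s <= 21 <= s + 18}
        assert {h.start for h in hits} == set(range(1, 40 - 19 + 2)) - dropped

    def test_prepending_seven_residues_shifts_starts_not_scores(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng)
        seq = random_seq(rng, 120)
        before = scan_sequence(seq, m)
        after = scan_sequence(random_seq(rng, 7) + seq, m)
        shifted = {h.start: h.score for h in after}
        for h in before:
            assert shifted[h.start + 7] == h.score

    @given(st.integers(0, 500))
    def test_single_cell_increase_never_decreases_any_score(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng)
        seq = random_seq(rng, 60)
        base = [h.score for h in scan_sequence(seq, m)]
        tbl = m.table.copy()
        # bump a strictly positive cell, so the per-position zero
        # (required for validity) is preserved
        positive = [
            (aa, pos)
            for aa in AA
            for pos in tbl.columns
            if tbl.at[aa, pos] > 0
        ]
        aa, pos = positive[rng.integers(len(positive))]
        tbl.at[aa, pos] += 1.0
        bumped = make_matrix(tbl.values)
        up = [h.score for h in scan_sequence(seq, bumped)]
        assert all(u >= b for u, b in zip(up, base))


class TestBestHits:
    def test_single_window_protein_returns_that_hit(self, conventional_matrix):
        hits = scan_sequence("A" * 19, conventional_matrix)
        assert best_hits(hits) == hits

    def test_two_planted_ideal_motifs_recovered_in_position_order(
        self, default_matrices, conventional_matrix
    ):
        ideal = ideal_sequence(conventional_matrix)
        rng = np.random.default_rng(2)
        # two ideal plants 40 apart inside a high-scoring background
        records, truth = gen_proteome(
            n_proteins=1,
            n_planted_conventional=1,
            n_planted_phospho=0,
            degradation_penalty_budget=0.0,
            matrix_pair=default_matrices,
            seed=2,
        )
        pid, seq = records[0]
        plant = truth.planted[0]
        # add a second ideal motif 40 residues after the first, then
        # re-check it does not collide with sequence end
        pos2 = plant.start - 1 + 40
        if pos2 + 19 <= len(seq):
            seq = seq[:pos2] + ideal + seq[pos2 + 19 :]
            expected_starts = sorted([plant.start, pos2 + 1])
        else:
            pos2 = plant.start - 1 - 40
            seq = seq[:pos2] + ideal + seq[pos2 + 19 :]
            expected_starts = sorted([plant.start, pos2 + 1])
        hits = scan_sequence(seq, conventional_matrix, protein_id=pid)
        top = best_hits(hits, k=2)
        assert sorted(h.start for h in top) == expected_starts
        assert [h.score for h in top] == [0.0, 0.0]

    def test_shifted_windows_of_one_motif_cannot_fill_slot_two(
        self, conventional_matrix
    ):
        ideal = ideal_sequence(conventional_matrix)
        rng = np.random.default_rng(9)
        flank = "".join(rng.choice(list("KRH"), size=30))  # high-penalty bg
        seq = flank + ideal + flank
        hits = scan_sequence(seq, conventional_matrix)
        top = best_hits(hits, k=2)
        assert top[0].start == 31 and top[0].score == 0.0
        if len(top) > 1:
            # slot 2 must be core-disjoint from the winner
            lo1, hi1 = top[0].core_interval
            lo2, hi2 = top[1].core_interval
            assert hi2 < lo1 or lo2 > hi1
            # and must be the best among core-disjoint windows
            disjoint = [
                h
                for h in hits
                if h.core_interval[1] < lo1 or h.core_interval[0] > hi1
            ]
            assert top[1].score == min(h.score for h in disjoint)

    def test_rejects_k_below_one_and_mixed_proteins(self, conventional_matrix):
        hits = scan_sequence("A" * 19, conventional_matrix, protein_id="p1")
        with pytest.raises(ValueError, match="k must be"):
            best_hits(hits, k=0)
        other = scan_sequence("A" * 19, conventional_matrix, protein_id="p2")
        with pytest.raises(ValueError, match="one protein"):
            best_hits(hits + other)


class TestClassifySignificant:
    @pytest.mark.parametrize(
        "score,expected", [(0.0, True), (2.5, True), (2.6, False)]
    )
    def test_closed_band(self, score, expected):
        assert classify_significant(score) is expected

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            classify_significant(-0.1)


class TestScanProteome:
    def test_planted_proteome_significance_matches_truth(
        self, default_matrices
    ):
        records, truth = gen_proteome(
            n_proteins=10,
            n_planted_conventional=2,
            n_planted_phospho=2,
            degradation_penalty_budget=1.0,
            matrix_pair=default_matrices,
            seed=4,
        )
        results = scan_proteome(records, default_matrices)
        sig = {r.protein_id for r in results if r.significant}
        assert sig == set(truth.planted_protein_ids)

    def test_threshold_zero_keeps_only_exact_ideal_plants(
        self, default_matrices
    ):
        records, truth = gen_proteome(
            n_proteins=6,
            n_planted_conventional=2,
            n_planted_phospho=0,
            degradation_penalty_budget=0.0,
            matrix_pair=default_matrices,
            seed=5,
        )
        results = scan_proteome(records, default_matrices, threshold=0.0)
        sig = {r.protein_id for r in results if r.significant}
        assert sig == set(truth.planted_protein_ids)

    def test_planted_start_and_score_recovered(self, default_matrices):
        records, truth = gen_proteome(
            n_proteins=5,
            n_planted_conventional=1,
            n_planted_phospho=0,
            degradation_penalty_budget=0.0,
            matrix_pair=default_matrices,
            seed=6,
        )
        results = {r.protein_id: r for r in scan_proteome(records, default_matrices)}
        plant = truth.planted[0]
        best = results[plant.protein_id].best[MotifClass.CONVENTIONAL][0]
        assert best.start == plant.start
        assert best.score == 0.0

    def test_duplicate_ids_rejected_and_empty_input_warns(
        self, default_matrices, caplog
    ):
        with pytest.raises(ValueError, match="duplicate"):
            scan_proteome(
                [("p", "A" * 19), ("p", "C" * 19)], default_matrices
            )
        with caplog.at_level(logging.WARNING):
            assert scan_proteome([], default_matrices) == []
        assert "no records" in caplog.text

    def test_long_hit_table_has_declared_columns(self, default_matrices):
        records, _ = gen_proteome(
            n_proteins=3,
            n_planted_conventional=1,
            n_planted_phospho=0,
            matrix_pair=default_matrices,
            seed=8,
        )
        tbl = hits_to_table(scan_proteome(records, default_matrices))
        assert list(tbl.columns) == [
            "protein_id", "class", "rank", "start", "core_start",
            "window_seq", "score", "significant",
        ]
        assert (tbl["core_start"] == tbl["start"] + 6).all()
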