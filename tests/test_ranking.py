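"""Consensus filter, expression threshold and lexicographic ranking."""

import csv

import numpy as np
import pytest

from adc_target_vault import synth
from adc_target_vault.ranking import (
    export_ranking,
    healthy_tissue_counts,
    patient_fraction,
    rank_targets,
    tm_consensus_filter,
)
from adc_target_vault.store import Vault
from adc_target_vault.types import (
    CancerIHCSummary,
    HealthyIHCObservation,
    ProteinRecord,
    TMPrediction,
    ValidationError,
)


def _preds(counts):
    names = synth.PREDICTORS
    return [TMPrediction("P", names[i], c) for i, c in enumerate(counts)]


class TestTMConsensusFilter:
    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 1, 1, 1, 7], True),   # 5 of 6 agree
        ([1, 1, 1, 1, 2, 7], False),  # only 4 agree
        ([1, 1, 1, 1, 1, 1], True),
        ([0, 0, 0, 0, 0, 0], False),
    ])
    def test_five_of_six_single_segment_rule(self, counts, expected):
        assert tm_consensus_filter(_preds(counts)) is expected

    def test_missing_predictor_counts_as_disagreement(self):
        # 5 predictors present, all agreeing, still reaches the quorum;
        # 4 present cannot.
        assert tm_consensus_filter(_preds([1, 1, 1, 1, 1])) is True
        assert tm_consensus_filter(_preds([1, 1, 1, 1])) is False

    def test_duplicate_predictor_labels_rejected(self):
        preds = _preds([1, 1, 1, 1, 1, 1])
        preds[5] = TMPrediction("P", preds[0].predictor, 1)
        with pytest.raises(ValidationError, match="duplicate"):
            tm_consensus_filter(preds)

    def test_required_segments_parameter(self):
        # Looking for 7-TM receptors instead of single-pass ones.
        assert tm_consensus_filter(_preds([7, 7, 7, 7, 7, 1]),
                                   required_segments=7) is True


class TestPatientFraction:
    @pytest.mark.parametrize("counts,frac", [
        ((5, 6, 5, 4), 0.55),
        ((0, 0, 10, 10), 0.0),
        ((22, 0, 0, 0), 1.0),
    ])
    def test_fraction(self, counts, frac):
        assert patient_fraction(CancerIHCSummary("P", "oc", *counts)) == frac


def _mini_vault(healthy_levels, cancer_counts):
    """Vault with one protein, given per-(tissue, cell) levels and counts."""
    v = Vault.create()
    v.ingest_records(
        [ProteinRecord("P1", "G1", "S1")],
        tms=_preds_for("P1"),
        healthy=[HealthyIHCObservation("P1", t, ct, lvl)
                 for (t, ct), lvl in healthy_levels.items()],
        cancer=[CancerIHCSummary("P1", "oc", *cancer_counts)],
    )
    return v


def _preds_for(pid, counts=(1, 1, 1, 1, 1, 1)):
    return [TMPrediction(pid, synth.PREDICTORS[i], c) for i, c in enumerate(counts)]


class TestHealthyTissueCounts:
    def test_counts_over_per_tissue_maxima(self):
        v = _mini_vault({("brain", "x"): "High", ("liver", "x"): "Medium",
                         ("lung", "x"): "Low"}, (12, 0, 0, 10))
        assert healthy_tissue_counts(v, "P1") == (2, 1, 1)
        v.close()

    def test_k1_equals_k2_plus_k3_under_max_collapse(self, vault):
        for pid in vault.protein_ids():
            k1, k2, k3 = healthy_tissue_counts(vault, pid)
            assert k1 == k2 + k3

    def test_no_healthy_rows_counts_zero_with_data_gap(self):
        v = _mini_vault({}, (12, 0, 0, 10))
        assert healthy_tissue_counts(v, "P1") == (0, 0, 0)
        targets = rank_targets(v, "oc")
        assert targets[0].data_gap is True
        v.close()

    def test_per_cell_type_mode_counts_pairs(self):
        v = _mini_vault({("liver", "a"): "High", ("liver", "b"): "Medium"},
                        (12, 0, 0, 10))
        assert healthy_tissue_counts(v, "P1", "max") == (1, 1, 0)
        assert healthy_tissue_counts(v, "P1", "per_cell_type") == (2, 1, 1)
        v.close()


def _vault_from_table(rows):
    """rows: list of (pid, symbol, tm_counts, healthy tissue levels, cancer)."""
    v = Vault.create()
    proteins, tms, healthy, cancer = [], [], [], []
    for pid, sym, tm_counts, tissue_levels, counts in rows:
        proteins.append(ProteinRecord(pid, f"ENS_{pid}", sym))
        tms.extend(_preds_for(pid, tm_counts))
        for i, (tissue, lvl) in enumerate(tissue_levels.items()):
            healthy.append(HealthyIHCObservation(pid, tissue, "cells", lvl))
        cancer.append(CancerIHCSummary(pid, "oc", *counts))
    v.ingest_records(proteins, tms, healthy, cancer)
    return v


ONE_TM = (1, 1, 1, 1, 1, 2)


class TestRankTargets:
    def test_k4_descends_within_equal_healthy_keys(self):
        v = _vault_from_table([
            ("A", "SA", ONE_TM, {}, (18, 0, 0, 2)),   # K4 = 0.9
            ("B", "SB", ONE_TM, {}, (12, 0, 0, 8)),   # K4 = 0.6
        ])
        out = rank_targets(v, "oc")
        assert [t.protein_id for t in out] == ["A", "B"]
        v.close()

    def test_k1_ascending_dominates_k4(self):
        v = _vault_from_table([
            ("A", "SA", ONE_TM, {"liver": "High"}, (20, 0, 0, 0)),
            ("B", "SB", ONE_TM, {}, (11, 0, 9, 0)),  # 0.55 but clean healthy
        ])
        out = rank_targets(v, "oc")
        assert [t.protein_id for t in out] == ["B", "A"]
        v.close()

    def test_threshold_is_strict(self):
        v = _vault_from_table([
            ("A", "SA", ONE_TM, {}, (11, 0, 11, 0)),   # exactly 0.5 -> excluded
            ("B", "SB", ONE_TM, {}, (12, 0, 10, 0)),   # > 0.5 -> kept
        ])
        out = rank_targets(v, "oc")
        assert [t.protein_id for t in out] == ["B"]
        v.close()

    def test_tm_filter_soundness(self, vault):
        out = rank_targets(vault, "ovarian cancer", apply_tm_filter=True)
        assert out and all(t.passed_tm_filter for t in out)

    def test_filter_order_independent(self, vault):
        """Expression threshold and TM filter commute (both are filters)."""
        both = rank_targets(vault, "ovarian cancer", apply_tm_filter=True)
        loose = rank_targets(vault, "ovarian cancer", apply_tm_filter=False)
        surviving = [t.protein_id for t in loose if t.passed_tm_filter]
        assert sorted(surviving) == sorted(t.protein_id for t in both)

    def test_ranks_consecutive_from_one(self, vault):
        out = rank_targets(vault, "ovarian cancer")
        assert [t.rank for t in out] == list(range(1, len(out) + 1))

    def test_empty_candidate_set_is_empty_list(self):
        v = _vault_from_table([("A", "SA", ONE_TM, {}, (0, 0, 0, 10))])
        assert rank_targets(v, "oc") == []
        v.close()

    def test_monotonicity_raising_healthy_level_cannot_improve_rank(self):
        rows = [
            ("A", "SA", ONE_TM, {"liver": "Low"}, (15, 0, 0, 5)),
            ("B", "SB", ONE_TM, {"liver": "Low"}, (14, 0, 0, 6)),
            ("C", "SC", ONE_TM, {"brain": "Medium"}, (20, 0, 0, 0)),
        ]
        v = _vault_from_table(rows)
        base_rank = {t.protein_id: t.rank for t in rank_targets(v, "oc")}
        v.close()
        rows[0] = ("A", "SA", ONE_TM, {"liver": "High"}, (15, 0, 0, 5))
        v = _vault_from_table(rows)
        worse_rank = {t.protein_id: t.rank for t in rank_targets(v, "oc")}
        assert worse_rank["A"] >= base_rank["A"]
        v.close()

    def test_monotonicity_raising_patient_level_cannot_worsen_rank(self):
        rows = [
            ("A", "SA", ONE_TM, {}, (11, 1, 5, 3)),
            ("B", "SB", ONE_TM, {}, (11, 2, 4, 3)),
        ]
        v = _vault_from_table(rows)
        base = {t.protein_id: t.rank for t in rank_targets(v, "oc")}
        v.close()
        # One of A's Low patients moves up to Medium.
        rows[0] = ("A", "SA", ONE_TM, {}, (11, 2, 4, 3))
        v = _vault_from_table(rows)
        after = {t.protein_id: t.rank for t in rank_targets(v, "oc")}
        assert after["A"] <= base["A"]
        v.close()


class TestExportRanking:
    def test_csv_round_trip(self, vault, tmp_path):
        out = rank_targets(vault, "ovarian cancer")
        path = tmp_path / "ranking.csv"
        export_ranking(out, path)
        with open(path) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(out)
        for row, t in zip(rows, out):
            assert int(row["rank"]) == t.rank
            assert row["protein_id"] == t.protein_id
            assert (int(row["K1"]), int(row["K2"]), int(row["K3"])) == (
                t.keys.k1, t.keys.k2, t.keys.k3)
            assert float(row["K4"]) == pytest.approx(t.keys.k4, abs=5e-5)

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        export_ranking([], path)
        assert path.read_text().splitlines() == [
            "rank,protein_id,gene_symbol,K1,K2,K3,K4,passed_tm_filter,data_gap"]


@pytest.mark.parametrize("seed", range(10))
def test_rank_targets_matches_brute_force_oracle(seed):
    """Full ranking equals an independent 4-key sort over the raw records."""
    from oracles import brute_force_rank

    rng = np.random.default_rng(seed)
    cfg = synth.FixtureConfig(
        seed=seed, n_proteins=int(rng.integers(20, 80)),
        n_planted_targets=int(rng.integers(0, 6)),
        decoy_multi_tm_frac=float(rng.uniform(0.2, 0.9)))
    proteins, tms = synth.gen_proteome(cfg)
    healthy, cancer = synth.gen_expression(cfg, proteins)
    apply_tm = bool(rng.integers(0, 2))
    expected = brute_force_rank(proteins, tms, healthy, cancer,
                                "ovarian cancer", apply_tm_filter=apply_tm)
    with Vault.create() as v:
        v.ingest_records(proteins, tms, healthy, cancer)
        got = rank_targets(v, "ovarian cancer", apply_tm_filter=apply_tm)
    assert [(t.protein_id, (t.keys.k1, t.keys.k2, t.keys.k3, t.keys.k4))
            for t in got] == expected
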