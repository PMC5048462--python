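import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fitmeta.datasets import (
    MARKER_STUDY_IDS,
    PUBLISHED_VIRT,
    load_marker_compendium,
    marker_compendium_config,
)
from fitmeta.virtual import (
    StudyMatrix,
    StudyMeta,
    VirtConfig,
    build_virtual_dataset,
    compute_virt,
    rank_markers,
    round_half_away,
    summarize_dataset,
    virt_records,
)

CFG = VirtConfig(n_total_up=14, n_total_down=12)
STUDIES_14 = [
    StudyMeta(f"S{i:02d}", induced_only=(i > 12)) for i in range(1, 15)
]  # last two induced-only -> 12 down-eligible


def record_for(calls, config=CFG, studies=None):
    studies = studies if studies is not None else STUDIES_14
    return compute_virt(calls, studies, config, gene_id="G")


class TestComputeVirt:
    def test_unanimous_up(self):
        r = record_for([1] * 14)
        assert (r.abs_occ, r.sum_reg, r.rat) == (14, 14, 1.0)
        assert r.virt == 1.0
        assert r.passes and r.direction == "up"

    def test_thirteen_up_one_zero(self):
        r = record_for([1] * 13 + [0])
        assert r.virt == pytest.approx(13 / 14)
        assert r.virt_rounded == 0.93

    def test_ten_down_two_zero(self):
        calls = [-1, 0, -1, -1, -1, -1, -1, -1, -1, -1, -1, 0, 0, 0]
        r = record_for(calls)
        assert (r.abs_occ, r.sum_reg, r.rat) == (10, -10, 1.0)
        assert r.virt == pytest.approx(-10 / 12)
        assert r.virt_rounded == -0.83
        assert r.direction == "down"

    def test_mixed_directions_fail_rat(self):
        calls = [1] * 7 + [-1] * 3 + [0] * 4
        studies = [StudyMeta(f"S{i:02d}") for i in range(1, 15)]
        r = record_for(calls, VirtConfig(n_total_up=14, n_total_down=14), studies)
        assert (r.abs_occ, r.sum_reg) == (10, 4)
        assert r.rat == pytest.approx(0.4)
        assert not r.passes and r.direction == "none"

    def test_all_zero_row(self):
        r = record_for([0] * 14)
        assert not r.passes
        assert r.virt == 0.0
        assert r.direction == "none"

    def test_unanimous_down_gives_minus_one(self):
        calls = [-1] * 12 + [0, 0]  # last two studies induced-only
        r = record_for(calls)
        assert r.virt == -1.0

    def test_induced_only_minus_one_rejected(self):
        calls = [0] * 13 + [-1]
        with pytest.raises(ValueError, match="induced-only"):
            record_for(calls)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="expected 14"):
            record_for([1] * 5)

    @settings(max_examples=200)
    @given(calls=st.lists(st.sampled_from([-1, 0, 1]), min_size=12, max_size=12))
    def test_bound_and_sign_invariants(self, calls):
        studies = [StudyMeta(f"S{i:02d}") for i in range(1, 13)]
        r = record_for(calls, VirtConfig(n_total_up=12, n_total_down=12), studies)
        assert abs(r.virt) <= 1.0 + 1e-12
        assert abs(r.sum_reg) <= r.abs_occ <= 12
        assert np.sign(r.virt) == np.sign(r.sum_reg)
        if r.abs_occ:
            assert 0 <= r.rat <= 1

    def test_contradiction_penalty(self):
        # fixed ABS=10: growing the minority strictly shrinks |VIRT|
        studies = [StudyMeta(f"S{i:02d}") for i in range(1, 15)]
        cfg = VirtConfig(n_total_up=14, n_total_down=14)
        prev = None
        for minority in range(0, 5):
            calls = [1] * (10 - minority) + [-1] * minority + [0] * 4
            v = abs(compute_virt(calls, studies, cfg).virt)
            if prev is not None:
                assert v < prev
            prev = v

    def test_agreement_monotonicity(self):
        # converting one 0 to the majority direction never decreases |VIRT|
        studies = [StudyMeta(f"S{i:02d}") for i in range(1, 15)]
        cfg = VirtConfig(n_total_up=14, n_total_down=14)
        base = [1] * 6 + [-1] * 2 + [0] * 6
        upgraded = [1] * 7 + [-1] * 2 + [0] * 5
        assert abs(compute_virt(upgraded, studies, cfg).virt) >= abs(
            compute_virt(base, studies, cfg).virt
        )

    def test_induced_only_flag_never_changes_up_genes(self):
        calls = [1] * 10 + [0] * 4
        up_cfg = VirtConfig(n_total_up=14, n_total_down=12)
        alt_cfg = VirtConfig(n_total_up=14, n_total_down=10)
        assert record_for(calls, up_cfg).virt == record_for(calls, alt_cfg).virt

    def test_round_half_away(self):
        assert round_half_away(0.005) == 0.01
        assert round_half_away(-0.005) == -0.01
        assert round_half_away(0.8333) == 0.83
        assert round_half_away(0.9285714) == 0.93


class TestMarkerCompendium:
    """The bundled 25-gene reference matrix reproduces the published scores."""

    def test_every_published_virt_value(self):
        matrix = load_marker_compendium()
        records = virt_records(matrix, marker_compendium_config())
        assert len(records) == 25
        for r in records:
            assert r.virt_rounded == pytest.approx(PUBLISHED_VIRT[r.gene_id]), r.gene_id
            assert r.passes

    def test_matrix_shape_and_flags(self):
        matrix = load_marker_compendium()
        assert list(matrix.values.columns) == MARKER_STUDY_IDS
        assert matrix.n_induced_only == 2
        assert matrix.default_config().n_total_down == 12

    def test_top_ranked_markers(self):
        matrix = load_marker_compendium()
        records = virt_records(matrix, marker_compendium_config())
        top_up = rank_markers(records, "up", 2)
        assert [r.gene_id for r in top_up] == ["AT3G07720", "AT3G58810"]
        assert all(r.virt_rounded == 1.00 for r in top_up)
        top_down = rank_markers(records, "down", 1)
        assert top_down[0].gene_id == "AT5G01600"
        assert top_down[0].virt_rounded == -0.83


class TestBuildVirtualDataset:
    def test_single_study_matrix_passes_nothing(self):
        studies = [StudyMeta("S1")]
        values = pd.DataFrame({"S1": [1, -1, 0]}, index=["A1", "A2", "A3"])
        matrix = StudyMatrix(studies, values)
        assert build_virtual_dataset(matrix) == []

    def test_pass_set_matches_per_gene_oracle(self, rng):
        n_genes, n_studies = 200, 14
        values = rng.integers(-1, 2, size=(n_genes, n_studies))
        induced_only = [False] * 12 + [True] * 2
        values[:, 12:][values[:, 12:] == -1] = 0
        genes = [f"AT{i}G{i:05d}" for i in range(n_genes)]
        studies = [
            StudyMeta(f"S{i:02d}", induced_only=flag)
            for i, flag in enumerate(induced_only, start=1)
        ]
        matrix = StudyMatrix(studies, pd.DataFrame(values, index=genes, columns=[s.study_id for s in studies]))
        cfg = matrix.default_config()
        ranked = build_virtual_dataset(matrix, cfg)

        # oracle: recompute each gene from first principles
        expected = set()
        for gene, row in zip(genes, values):
            abs_occ = int((row != 0).sum())
            total = int(row.sum())
            if abs_occ == 0:
                continue
            rat = abs(total) / abs_occ
            n = 14 if total > 0 else 12
            virt = total / n * rat
            if abs(total) >= 2 and rat >= 0.5 and abs(virt) >= 0.25:
                expected.add(gene)
        assert {r.gene_id for r in ranked} == expected

    def test_ranking_matches_reference_sort(self, rng):
        values = rng.integers(-1, 2, size=(50, 12))
        genes = [f"AT1G{i:05d}" for i in range(50)]
        studies = [StudyMeta(f"S{i:02d}") for i in range(1, 13)]
        matrix = StudyMatrix(studies, pd.DataFrame(values, index=genes, columns=[s.study_id for s in studies]))
        ranked = build_virtual_dataset(matrix, VirtConfig(n_total_up=12, n_total_down=12))
        resorted = sorted(ranked, key=lambda r: (-abs(r.virt), -r.abs_occ, r.gene_id))
        assert [r.gene_id for r in ranked] == [r.gene_id for r in resorted]


class TestSummarizeAndRank:
    def test_two_record_summary(self):
        studies = [StudyMeta(f"S{i}") for i in range(1, 5)]
        cfg = VirtConfig(n_total_up=4, n_total_down=4)
        up = compute_virt([1, 1, 0, 0], studies, cfg, "A")
        down = compute_virt([-1, -1, -1, 0], studies, cfg, "B")
        summary = summarize_dataset([up, down])
        assert summary["n_up"] == 1 and summary["n_down"] == 1
        assert summary["mean_abs_virt"] == pytest.approx((abs(up.virt) + abs(down.virt)) / 2)

    def test_all_failing_summary(self):
        studies = [StudyMeta(f"S{i}") for i in range(1, 5)]
        cfg = VirtConfig(n_total_up=4, n_total_down=4)
        records = [compute_virt([0, 0, 0, 0], studies, cfg, "A")]
        summary = summarize_dataset(records)
        assert summary["n_pass"] == 0
        assert summary["mean_abs_virt"] is None

    def test_mean_matches_brute_force(self, rng):
        studies = [StudyMeta(f"S{i:02d}") for i in range(1, 15)]
        cfg = VirtConfig(n_total_up=14, n_total_down=14)
        records = [
            compute_virt(rng.integers(-1, 2, size=14), studies, cfg, f"G{i}")
            for i in range(50)
        ]
        summary = summarize_dataset(records)
        passing = [abs(r.virt) for r in records if r.passes]
        if passing:
            assert summary["mean_abs_virt"] == pytest.approx(sum(passing) / len(passing))

    def test_reference_coverage(self):
        studies = [StudyMeta(f"S{i}") for i in range(1, 5)]
        cfg = VirtConfig(n_total_up=4, n_total_down=4)
        records = [
            compute_virt([1, 1, 1, 1], studies, cfg, "A"),
            compute_virt([1, 1, 1, 0], studies, cfg, "B"),
        ]
        summary = summarize_dataset(records, reference_genes={"a"})
        assert summary["reference_coverage"] == pytest.approx(0.5)

    def test_rank_k_larger_than_pass_set(self):
        studies = [StudyMeta(f"S{i}") for i in range(1, 5)]
        cfg = VirtConfig(n_total_up=4, n_total_down=4)
        records = [compute_virt([1, 1, 1, 1], studies, cfg, "A")]
        assert len(rank_markers(records, "up", 10)) == 1

    def test_rank_invalid_k(self):
        with pytest.raises(ValueError, match="k must be positive"):
            rank_markers([], "up", 0)

    def test_rank_invalid_direction(self):
        with pytest.raises(ValueError, match="direction"):
            rank_markers([], "any", 1)


class TestStudyMatrixValidation:
    def test_induced_only_with_minus_one_rejected(self):
        studies = [StudyMeta("S1", induced_only=True)]
        values = pd.DataFrame({"S1": [-1]}, index=["AT1G00001"])
        with pytest.raises(ValueError, match="S1.*AT1G00001"):
            StudyMatrix(studies, values)

    def test_out_of_range_cell_rejected(self):
        studies = [StudyMeta("S1")]
        values = pd.DataFrame({"S1": [2]}, index=["AT1G00001"])
        with pytest.raises(ValueError, match="outside"):
            StudyMatrix(studies, values)

    def test_duplicate_gene_rejected(self):
        studies = [StudyMeta("S1")]
        values = pd.DataFrame({"S1": [1, 0]}, index=["AT1G00001", "at1g00001"])
        with pytest.raises(ValueError, match="duplicate gene"):
            StudyMatrix(studies, values)
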