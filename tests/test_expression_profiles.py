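import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lincscan.expression_profiles import (
    density_compare,
    expressed_set,
    neighbor_distances,
    settlement_contrast,
    stage_specific,
    tau,
    tissue_specific,
)
from lincscan.io_formats import (
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    SampleMeta,
    TranscriptModel,
)


def _matrix(rows: dict, samples):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[m.sample_id for m in samples])
    return ExpressionMatrix(df, samples)


TISSUE_SAMPLES = [SampleMeta(f"s{i}", tissue=t) for i, t in enumerate("abcd")]


class TestExpressedSet:
    def test_all_zero_excluded_boundary_included(self):
        m = _matrix({"z": [0, 0, 0, 0], "b": [0, 1.0, 0, 0]}, TISSUE_SAMPLES)
        assert expressed_set(m) == {"b"}

    def test_matches_row_max_oracle(self):
        rng = np.random.default_rng(0)
        rows = {f"f{i}": rng.uniform(0, 3, 4) for i in range(200)}
        m = _matrix(rows, TISSUE_SAMPLES)
        assert expressed_set(m) == {f for f, v in rows.items() if max(v) >= 1.0}


class TestTau:
    @pytest.mark.parametrize(
        "vec,expected",
        [((0, 0, 8, 0), 1.0), ((5, 5, 5, 5), 0.0), ((1, 2, 4), 0.625)],
    )
    def test_exact_values(self, vec, expected):
        assert tau(vec) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_and_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            tau((0, 0, 0))
        with pytest.raises(ValueError):
            tau((5,))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 1000), min_size=2, max_size=12).filter(
            lambda v: max(v) > 0
        ),
        st.floats(0.01, 100),
    )
    def test_scale_invariance_and_range(self, vec, c):
        t = tau(vec)
        assert 0.0 <= t <= 1.0 + 1e-12
        assert tau([c * x for x in vec]) == pytest.approx(t, abs=1e-9)

    def test_monotone_under_concentration(self):
        # moving mass from a minor tissue into the max tissue raises tau
        base = [10.0, 4.0, 3.0, 1.0]
        concentrated = [14.0, 0.0, 3.0, 1.0]
        assert tau(concentrated) > tau(base)


class TestTissueSpecific:
    def test_impossible_threshold_flags_nothing(self):
        m = _matrix({"f": [0, 0, 9, 0]}, TISSUE_SAMPLES)
        _, counts = tissue_specific(m, tau_threshold=1.01)
        assert sum(counts.values()) == 0

    def test_unexpressed_feature_absent(self):
        m = _matrix({"f": [0.1, 0.2, 0.3, 0.1], "g": [0, 0, 9, 0]}, TISSUE_SAMPLES)
        results, _ = tissue_specific(m)
        assert "f" not in results and "g" in results

    def test_multi_sample_tissues_averaged(self):
        samples = [
            SampleMeta("s1", tissue="gill"),
            SampleMeta("s2", tissue="gill"),
            SampleMeta("s3", tissue="mantle"),
        ]
        m = _matrix({"f": [4.0, 8.0, 0.0]}, samples)
        results, _ = tissue_specific(m)
        # per-tissue means: gill 6, mantle 0 -> tau = 1
        assert results["f"].tau == pytest.approx(1.0)
        assert results["f"].argmax_tissue == "gill"

    def test_planted_specific_lincs_recovered(self, default_scene, default_expression):
        tissue_matrix, _ = default_expression
        truth = default_scene.truth
        sub = tissue_matrix.subset(truth.planted_linc_ids)
        results, counts = tissue_specific(sub)
        flagged = {f for f, r in results.items() if r.tau > 0.95}
        assert flagged == set(truth.tissue_specific_map)
        for lid, tis in truth.tissue_specific_map.items():
            assert results[lid].argmax_tissue == tis
        assert sum(counts.values()) == len(truth.tissue_specific_map)


DEV_SAMPLES = [
    SampleMeta("d1", stage="embryo"),
    SampleMeta("d2", stage="embryo"),
    SampleMeta("d3", stage="spat"),
    SampleMeta("d4", stage="spat"),
]


class TestStageCalls:
    def test_single_stage_specific(self):
        m = _matrix({"f": [5, 8, 0, 0.2]}, DEV_SAMPLES)
        (call,) = stage_specific(m)
        assert call.specific_stage == "embryo"

    def test_two_stages_not_specific(self):
        m = _matrix({"f": [5, 0, 7, 0]}, DEV_SAMPLES)
        (call,) = stage_specific(m)
        assert call.stages_expressed == {"embryo", "spat"}
        assert call.specific_stage is None

    def test_all_zero_no_stages(self):
        m = _matrix({"f": [0, 0, 0, 0]}, DEV_SAMPLES)
        (call,) = stage_specific(m)
        assert call.stages_expressed == set()

    def test_planted_stage_specific_recovered(self, default_scene, default_expression):
        _, dev = default_expression
        truth = default_scene.truth
        calls = stage_specific(dev.subset(truth.planted_linc_ids))
        called = {c.feature_id: c.specific_stage for c in calls if c.specific_stage}
        assert called == truth.stage_specific_map


class TestSettlement:
    def test_on_off_classification(self):
        m = _matrix({"on_a": [0, 0, 10, 0], "weak": [0, 0, 3, 0]}, DEV_SAMPLES)
        on_spat, on_embryo = settlement_contrast(m, "spat", "embryo")
        assert on_spat == {"on_a"}
        assert on_embryo == set()

    def test_missing_stage_rejected(self):
        m = _matrix({"f": [1, 1, 1, 1]}, DEV_SAMPLES)
        with pytest.raises(ValueError, match="veliger"):
            settlement_contrast(m, "veliger", "spat")

    def test_planted_settlement_sets_recovered(self, default_scene, default_expression):
        _, dev = default_expression
        truth = default_scene.truth
        a, b = settlement_contrast(
            dev.subset(truth.planted_linc_ids), "pediveliger", "spat"
        )
        assert a == truth.settlement_on_a
        assert b == truth.settlement_on_b


class TestDensityCompare:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        dc = density_compare(x, x)
        assert dc.ks_statistic == 0.0
        assert dc.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        dc = density_compare([0, 0, 0], [7, 7, 7])
        assert dc.ks_statistic == 1.0

    def test_ks_statistic_matches_ecdf_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.lognormal(0.5, 1.0, 80)
        b = rng.lognormal(1.5, 1.0, 90)
        dc = density_compare(a, b)
        la, lb = np.log2(a + 1), np.log2(b + 1)
        grid = np.sort(np.concatenate([la, lb]))
        f1 = np.searchsorted(np.sort(la), grid, side="right") / la.size
        f2 = np.searchsorted(np.sort(lb), grid, side="right") / lb.size
        assert dc.ks_statistic == pytest.approx(np.max(np.abs(f1 - f2)), abs=1e-12)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            density_compare([1.0], [1.0, 2.0])


class TestNeighborDistances:
    ann = GenomeAnnotation([Gene("g1", "chr1", "+", 1000, 2000)])

    def _linc(self, start, end, tid="l1"):
        return TranscriptModel(tid, "chr1", ".", [(start, end)])

    def test_gap_distance(self):
        results, frac, genes = neighbor_distances([self._linc(5000, 5300)], self.ann)
        assert results[0].distance_bp == 3000
        assert results[0].within_10kb
        assert frac == 1.0 and genes == {"g1"}

    def test_beyond_window(self):
        results, frac, genes = neighbor_distances([self._linc(12500, 12800)], self.ann)
        assert results[0].distance_bp == 10500
        assert not results[0].within_10kb
        assert frac == 0.0 and genes == set()

    def test_overlap_distance_zero(self):
        results, _, _ = neighbor_distances([self._linc(1500, 1600)], self.ann)
        assert results[0].distance_bp == 0

    def test_annotation_free_chromosome_excluded(self):
        t = TranscriptModel("lx", "chrZ", ".", [(0, 300)])
        with pytest.warns(UserWarning, match="chrZ"):
            results, _, _ = neighbor_distances([t], self.ann)
        assert results == []
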