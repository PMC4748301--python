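import numpy as np
import pytest

from lincscan import coexpression as cx
from lincscan.expression_profiles import tau
from lincscan.io_formats import extract_sequence
from lincscan.pipeline_filters import longest_orf
from lincscan.synthetic_data import (
    SimulationConfig,
    SimulationError,
    module_eigen_profiles,
    simulate_expression,
    simulate_genome,
)
from tests.test_pipeline_filters import brute_force_longest_orf

SMALL = dict(
    n_coding_genes=30,
    n_linc_loci=8,
    n_decoys_per_class=3,
    chrom_length=1_200_000,
    n_conserved_all=2,
    n_conserved_one=2,
    n_tissue_specific=2,
    n_stage_specific=2,
    n_settlement_each=1,
    module_spec=((12, 1), (12, -1)),
    lincs_per_module=1,
)


@pytest.fixture(scope="module")
def small_scene():
    return simulate_genome(SimulationConfig(seed=7, **SMALL))


class TestGenomeGeneration:
    def test_same_seed_reproduces_bytes(self):
        cfg = SimulationConfig(seed=3, **SMALL)
        a = simulate_genome(cfg)
        b = simulate_genome(SimulationConfig(seed=3, **SMALL))
        assert a.genome == b.genome
        assert [t.transcript_id for t in a.assembly] == [
            t.transcript_id for t in b.assembly
        ]
        assert a.truth.planted_linc_ids == b.truth.planted_linc_ids

    def test_no_linc_config_yields_only_coding_and_decoys(self):
        cfg = SimulationConfig(
            seed=2,
            **{**SMALL, "n_linc_loci": 0, "n_conserved_all": 0, "n_conserved_one": 0,
               "n_tissue_specific": 0, "n_stage_specific": 0, "n_settlement_each": 0,
               "lincs_per_module": 0},
        )
        scene = simulate_genome(cfg)
        assert scene.truth.planted_linc_ids == []
        assert scene.truth.duplicate_pairs == []
        n_expected = cfg.n_coding_genes + 5 * cfg.n_decoys_per_class
        assert len(scene.assembly) == n_expected

    def test_planted_lincs_satisfy_their_filters(self, small_scene):
        truth = small_scene.truth
        by_id = {t.transcript_id: t for t in small_scene.assembly}
        for lid in truth.planted_linc_ids:
            seq = extract_sequence(small_scene.genome, by_id[lid])
            assert len(seq) >= 200
            orf = longest_orf(seq).longest_orf_aa
            assert orf < 100
            assert orf == brute_force_longest_orf(seq)

    def test_decoys_fail_their_filters(self, small_scene):
        truth = small_scene.truth
        by_id = {t.transcript_id: t for t in small_scene.assembly}
        genes = small_scene.annotation.genes
        for tid in truth.short_decoy_ids:
            assert by_id[tid].length < 200
        for tid in truth.long_orf_decoy_ids:
            seq = extract_sequence(small_scene.genome, by_id[tid])
            assert longest_orf(seq).longest_orf_aa >= 100
        for tid in truth.flank_decoy_ids:
            t = by_id[tid]
            assert any(
                t.start < g.end + 500 and g.start - 500 < t.end for g in genes
            )
        for tid in truth.inside_gene_decoy_ids:
            t = by_id[tid]
            assert any(g.start <= t.start and t.end <= g.end for g in genes)

    def test_duplicates_reference_planted_lincs(self, small_scene):
        truth = small_scene.truth
        planted = set(truth.planted_linc_ids)
        for dup, parent in truth.duplicate_pairs:
            assert parent in planted
            assert dup not in planted

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(seed=1, **{**SMALL, "chrom_length": 20_000})
        with pytest.raises(SimulationError, match="packing"):
            simulate_genome(cfg)

    def test_truth_classes_disjoint(self, small_scene):
        truth = small_scene.truth
        classes = [
            set(truth.planted_linc_ids),
            set(truth.short_decoy_ids),
            set(truth.inside_gene_decoy_ids),
            set(truth.flank_decoy_ids),
            set(truth.long_orf_decoy_ids),
            set(truth.housekeeping_like_ids),
            {d for d, _ in truth.duplicate_pairs},
        ]
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                assert not classes[i] & classes[j]


class TestExpressionGeneration:
    def test_same_seed_reproduces_matrices(self, small_scene):
        a_t, a_d = simulate_expression(small_scene.truth, small_scene.config)
        b_t, b_d = simulate_expression(small_scene.truth, small_scene.config)
        assert a_t.values.equals(b_t.values)
        assert a_d.values.equals(b_d.values)

    def test_planted_tau_guarantees(self, small_scene):
        tissue, _ = simulate_expression(small_scene.truth, small_scene.config)
        truth = small_scene.truth
        for fid in tissue.feature_ids:
            t = tau(tissue.values.loc[fid].to_numpy())
            if fid in truth.tissue_specific_map:
                assert t > 0.95
            else:
                assert t < 0.5

    def test_single_tissue_zero_elsewhere_gives_tau_one(self):
        row = np.zeros(9)
        row[4] = 17.0
        assert tau(row) == 1.0

    def test_module_members_track_eigen_profile(self, small_scene):
        _, dev = simulate_expression(small_scene.truth, small_scene.config)
        truth = small_scene.truth
        cfg = small_scene.config
        profiles = module_eigen_profiles(cfg.n_timepoints, len(cfg.module_spec))
        for fid, label in truth.module_assignment.items():
            if label == "background" or fid not in set(dev.feature_ids):
                continue
            m = int(label[1:]) - 1
            sign = truth.module_sign[label]
            x = np.log2(dev.values.loc[fid].to_numpy() + 1.0)
            r = np.corrcoef(x, sign * profiles[m])[0, 1]
            assert r >= 0.6

    def test_eigen_profiles_monotone_with_rank(self):
        for p in module_eigen_profiles(34, 3):
            rho, _ = cx.spearman(p, np.arange(1, 35, dtype=float))
            assert abs(rho) >= 0.9

    def test_noise_free_limit_gives_perfect_within_module_correlation(self, small_scene):
        from dataclasses import replace

        cfg = replace(small_scene.config, noise_sd=0.0, hub_noise_sd=0.0)
        _, dev = simulate_expression(small_scene.truth, cfg)
        truth = small_scene.truth
        members = [
            f
            for f, lab in truth.module_assignment.items()
            if lab == "M1" and f in set(dev.feature_ids)
        ]
        X = dev.values.loc[members].to_numpy()
        for i in range(1, len(members)):
            rho, _ = cx.spearman(X[0], X[i])
            assert abs(rho) == pytest.approx(1.0)

    def test_oversized_modules_rejected(self, small_scene):
        from dataclasses import replace

        cfg = replace(small_scene.config, module_spec=((10_000, 1),))
        with pytest.raises(SimulationError, match="module sizes"):
            simulate_genome(cfg)
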