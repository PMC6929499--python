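"""Association statistics, profiles, and the omnibus permutation test."""

import warnings

import numpy as np
import pytest

from phylopart import (
    ClusterAssignment,
    DistanceMatrix,
    dcor_stat,
    drop_infinite_sites_mutations,
    hhg_stat,
    mantel_stat,
    omnibus_permutation_p,
    rand_index,
    rank_distance_matrix,
    reconstruct_pp_region,
    rv_coefficient,
    simulate_genealogy,
)
from phylopart import test_asso_dist as asso_dist_profile
from phylopart import test_dend_asso_ri as dend_asso_ri_profile
from oracles import (
    dcor_oracle,
    hhg_oracle,
    mantel_oracle,
    rand_index_oracle,
    random_distance_matrix,
    rv_oracle,
)


def _dm(names, values):
    return DistanceMatrix(tuple(names), np.asarray(values, dtype=float))


def _names(n):
    return tuple(f"h{i}" for i in range(n))


class TestRandIndex:
    def test_identical_partitions(self):
        a = ClusterAssignment(_names(4), np.array([0, 0, 1, 1]), 2)
        assert rand_index(a, a) == 1.0

    def test_crossed_partitions_one_third(self):
        a = ClusterAssignment(_names(4), np.array([0, 0, 1, 1]), 2)
        b = ClusterAssignment(_names(4), np.array([0, 1, 0, 1]), 2)
        assert rand_index(a, b) == pytest.approx(1 / 3)

    def test_two_items_full_disagreement(self):
        a = ClusterAssignment(_names(2), np.array([0, 1]), 2)
        b = ClusterAssignment(_names(2), np.array([0, 0]), 1)
        assert rand_index(a, b) == 0.0

    def test_mismatched_names_rejected(self):
        a = ClusterAssignment(_names(3), np.array([0, 1, 1]), 2)
        b = ClusterAssignment(("x", "y", "z"), np.array([0, 1, 1]), 2)
        with pytest.raises(ValueError):
            rand_index(a, b)

    def test_alignment_by_name_not_order(self):
        a = ClusterAssignment(("a", "b", "c"), np.array([0, 0, 1]), 2)
        b = ClusterAssignment(("c", "b", "a"), np.array([1, 0, 0]), 2)
        assert rand_index(a, b) == 1.0

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 9))
            u = rng.integers(0, 3, size=n)
            v = rng.integers(0, 3, size=n)
            a = ClusterAssignment(_names(n), u, int(np.unique(u).size))
            b = ClusterAssignment(_names(n), v, int(np.unique(v).size))
            assert rand_index(a, b) == pytest.approx(
                rand_index_oracle(u.tolist(), v.tolist()), abs=0
            )
            from sklearn.metrics import rand_score

            assert rand_index(a, b) == pytest.approx(rand_score(u, v))


class TestDistanceStatistics:
    @pytest.mark.parametrize(
        "stat,oracle",
        [
            (mantel_stat, mantel_oracle),
            (rv_coefficient, rv_oracle),
            (dcor_stat, dcor_oracle),
            (hhg_stat, hhg_oracle),
        ],
        ids=["mantel", "rv", "dcor", "hhg"],
    )
    def test_matches_brute_force_oracle(self, rng, stat, oracle):
        for _ in range(25):
            n = int(rng.integers(5, 9))
            d1 = random_distance_matrix(rng, n)
            d2 = random_distance_matrix(rng, n)
            got = stat(_dm(_names(n), d1), _dm(_names(n), d2))
            assert got == pytest.approx(oracle(d1, d2), abs=1e-12)

    def test_self_comparison_is_one(self, rng):
        d = random_distance_matrix(rng, 6)
        dm = _dm(_names(6), d)
        assert mantel_stat(dm, dm) == pytest.approx(1.0)
        assert rv_coefficient(dm, dm) == pytest.approx(1.0)
        assert dcor_stat(dm, dm) == pytest.approx(1.0)

    def test_scale_and_affine_invariances(self, rng):
        d = random_distance_matrix(rng, 6)
        dm = _dm(_names(6), d)
        scaled = _dm(_names(6), 3.5 * d)
        assert rv_coefficient(dm, scaled) == pytest.approx(1.0)
        assert dcor_stat(dm, scaled) == pytest.approx(1.0)
        affine = 2.0 * d + 1.0
        np.fill_diagonal(affine, 0.0)
        # Mantel is invariant to positive affine maps of the off-diagonals
        assert mantel_stat(dm, _dm(_names(6), affine)) == pytest.approx(1.0)

    def test_joint_reordering_invariance(self, rng):
        n = 7
        d1 = random_distance_matrix(rng, n)
        d2 = random_distance_matrix(rng, n)
        perm = rng.permutation(n)
        names = _names(n)
        pnames = tuple(names[i] for i in perm)
        for stat in (mantel_stat, rv_coefficient, dcor_stat, hhg_stat):
            base = stat(_dm(names, d1), _dm(names, d2))
            reord = stat(
                _dm(pnames, d1[np.ix_(perm, perm)]),
                _dm(pnames, d2[np.ix_(perm, perm)]),
            )
            assert reord == pytest.approx(base, abs=1e-10)

    def test_mantel_constant_distances_rejected(self):
        flat = np.ones((4, 4)) - np.eye(4)
        d = random_distance_matrix(np.random.default_rng(0), 4)
        with pytest.raises(ValueError, match="constant"):
            mantel_stat(_dm(_names(4), flat), _dm(_names(4), d))

    def test_dcor_zero_matrix_convention(self):
        z = _dm(_names(4), np.zeros((4, 4)))
        d = _dm(_names(4), random_distance_matrix(np.random.default_rng(0), 4))
        assert dcor_stat(z, d) == 0.0

    def test_hhg_degenerate_equal_distances_zero(self):
        flat = np.ones((3, 3)) - np.eye(3)
        assert hhg_stat(_dm(_names(3), flat), _dm(_names(3), flat)) == 0.0

    def test_hhg_nonnegative(self, rng):
        for _ in range(10):
            d1 = random_distance_matrix(rng, 6)
            d2 = random_distance_matrix(rng, 6)
            assert hhg_stat(_dm(_names(6), d1), _dm(_names(6), d2)) >= 0


def _scan_and_names(rng, n_seq=12, n_snv=15):
    g = simulate_genealogy(n_seq, rng)
    hm = drop_infinite_sites_mutations(
        g, n_snv, np.arange(1, n_snv + 1) * 1000, rng
    )
    return hm, reconstruct_pp_region(hm)


class TestAssoDistProfiles:
    def test_self_comparator_gives_one_at_focal(self, rng):
        hm, scan = _scan_and_names(rng)
        target = scan.trees[7]
        cdmat = rank_distance_matrix(target)
        for method in ("dCor", "Mantel", "RV"):
            prof = asso_dist_profile(scan, cdmat, method, hapmat=hm)
            assert prof.values[7] == pytest.approx(1.0)

    def test_method_case_insensitive_and_unknown_rejected(self, rng):
        hm, scan = _scan_and_names(rng)
        cdmat = rank_distance_matrix(scan.trees[0])
        prof = asso_dist_profile(scan, cdmat, "mantel", hapmat=hm)
        assert prof.statistic == "Mantel"
        with pytest.raises(ValueError, match="dCor, HHG, Mantel, RV"):
            asso_dist_profile(scan, cdmat, "pearson", hapmat=hm)

    def test_no_permutations_no_p_value(self, rng):
        hm, scan = _scan_and_names(rng)
        prof = asso_dist_profile(
            scan, rank_distance_matrix(scan.trees[0]), "RV", hapmat=hm
        )
        assert prof.p_value is None

    def test_seeded_p_value_reproducible(self, rng):
        hm, scan = _scan_and_names(rng)
        cd = _dm(hm.hap_names, random_distance_matrix(rng, hm.n_seq))
        p1 = asso_dist_profile(scan, cd, "dCor", hapmat=hm, nperm=59, seed=11).p_value
        p2 = asso_dist_profile(scan, cd, "dCor", hapmat=hm, nperm=59, seed=11).p_value
        assert p1 == p2
        assert 1 / 60 <= p1 <= 1.0

    def test_hhg_profile_matches_per_tree_statistic(self, rng):
        hm, scan = _scan_and_names(rng, n_seq=8, n_snv=6)
        cd = _dm(hm.hap_names, random_distance_matrix(rng, hm.n_seq))
        prof = asso_dist_profile(scan, cd, "HHG", hapmat=hm)
        for t, v in zip(scan.trees, prof.values):
            assert v == pytest.approx(hhg_stat(rank_distance_matrix(t), cd))

    def test_profile_csv_written_with_p(self, rng, tmp_path):
        hm, scan = _scan_and_names(rng, n_seq=8, n_snv=6)
        cd = _dm(hm.hap_names, random_distance_matrix(rng, hm.n_seq))
        prof = asso_dist_profile(scan, cd, "RV", hapmat=hm, nperm=19, seed=1)
        prof.to_csv(tmp_path / "p.csv")
        text = (tmp_path / "p.csv").read_text()
        assert text.startswith("# omnibus_p=")
        assert text.count("\n") == 2 + len(scan)


class TestDendAssoRI:
    def test_comparator_equal_to_reconstructed_tree(self, rng):
        hm, scan = _scan_and_names(rng)
        prof = dend_asso_ri_profile(scan, scan.trees[4], k=3)
        assert prof.values[4] == pytest.approx(1.0)

    def test_premade_partition_accepted(self, rng):
        hm, scan = _scan_and_names(rng)
        comp = ClusterAssignment(
            hm.hap_names, np.arange(hm.n_seq) % 2, 2
        )
        prof = dend_asso_ri_profile(scan, comp, k=2)
        assert prof.values.shape == (len(scan),)

    def test_small_tree_falls_back_to_tip_partition_with_warning(self):
        from phylopart import create_hapmat, reconstruct_pp_region

        hm = create_hapmat(
            [[0, 0], [0, 0], [1, 1]], ["s1", "s2"], ["a", "b", "c"], [1, 2]
        )
        scan = reconstruct_pp_region(hm, min_window=1)
        comp = ClusterAssignment(("a", "b", "c"), np.array([0, 1, 2]), 3)
        with pytest.warns(UserWarning, match="tips"):
            prof = dend_asso_ri_profile(scan, comp, k=3)
        assert prof.values.shape == (2,)


class TestOmnibus:
    def test_add_one_formula_bounds(self):
        # a single permutation whose max ties the observed max gives p = 1
        p = omnibus_permutation_p(
            [0.5], lambda perm: [0.5], n_labels=4, nperm=1, seed=0
        )
        assert p == 1.0

    def test_extreme_observed_gives_minimum_p(self):
        p = omnibus_permutation_p(
            [10.0], lambda perm: [0.0], n_labels=4, nperm=999, seed=0
        )
        assert p == pytest.approx(1 / 1000)

    def test_null_p_values_roughly_uniform(self, rng):
        """Independent comparator: p should be ~uniform with mean ~0.5."""
        hm, scan = _scan_and_names(rng, n_seq=10, n_snv=8)
        ps = []
        for _ in range(60):
            cd = _dm(hm.hap_names, random_distance_matrix(rng, hm.n_seq))
            ps.append(
                asso_dist_profile(
                    scan, cd, "Mantel", hapmat=hm, nperm=39,
                    seed=int(rng.integers(2**31)),
                ).p_value
            )
        assert 0.35 < np.mean(ps) < 0.65

    def test_ri_null_calibration_smoke(self, rng):
        """Permuted comparator labels: RI omnibus p should not be degenerate."""
        hm, scan = _scan_and_names(rng, n_seq=10, n_snv=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = []
            for _ in range(20):
                labels = rng.permutation(np.arange(hm.n_seq) % 3)
                comp = ClusterAssignment(hm.hap_names, labels, 3)
                ps.append(
                    dend_asso_ri_profile(
                        scan, comp, k=3, nperm=39, seed=int(rng.integers(2**31))
                    ).p_value
                )
        assert min(ps) >= 1 / 40 and max(ps) <= 1.0
        assert 0.2 < np.mean(ps) < 0.8
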