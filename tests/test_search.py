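import numpy as np
import pytest
from scipy import special

from conftest import toy_config
from helpers import (
    brute_force_max_fitness,
    enumerate_decoded_pairs,
    fake_srp,
    fitness_oracle,
    truth_tagged_set,
)
from plastec.consistency import dice, tagged_voxel_set
from plastec.encoding import Chromosome, ROISearchSpace
from plastec.search import (
    ECConfig,
    bonferroni_filter,
    count_connections,
    detect_all_srps,
    fitness_zscore,
    mutate,
    run_ec_level,
    select_population_elitist,
)
from plastec.synthetic import (
    PlantedBlock,
    PlantedTruth,
    make_geometry,
    make_matrix_dataset,
    plant_block,
)


class TestFitness:
    @pytest.mark.parametrize(
        "nc1,nc2,tc,z,fit",
        [
            (100, 150, 1000, 50 / np.sqrt(90), 5.270462766947299),
            (200, 120, 400, -8.0, 8.0),
            (5, 5, 10, 0.0, 0.0),  # no change -> zero fitness
            (0, 0, 50, 0.0, 0.0),  # degenerate baseline, still no change
        ],
    )
    def test_hand_evaluated_cases(self, nc1, nc2, tc, z, fit):
        got_z, got_fit, ec2, sd = fitness_zscore(nc1, nc2, tc)
        assert got_z == pytest.approx(z, rel=1e-12)
        assert got_fit == pytest.approx(fit, rel=1e-12)
        if 0 < nc1 < tc:
            assert ec2 == nc1
            assert sd == pytest.approx(np.sqrt(tc * (nc1 / tc) * (1 - nc1 / tc)))

    def test_total_gain_from_empty_baseline_scores_high(self):
        z, fit, _, _ = fitness_zscore(0, 40, 100)
        assert z > 0 and fit > 5

    def test_invalid_counts_are_errors(self):
        with pytest.raises(ValueError):
            fitness_zscore(1, 1, 0)
        with pytest.raises(ValueError):
            fitness_zscore(-1, 0, 10)
        with pytest.raises(ValueError):
            fitness_zscore(0, 11, 10)


class TestCountConnections:
    def test_extremes_and_loop_oracle(self):
        rng = np.random.default_rng(0)
        pair = fake_srp(0, 0, size_a=3, size_b=4)
        assert count_connections(pair, np.zeros((6, 6), dtype=np.uint8)) == 0
        assert count_connections(pair, np.ones((6, 6), dtype=np.uint8)) == 12
        m = (rng.random((6, 6)) < 0.4).astype(np.uint8)
        manual = sum(
            int(m[a, b]) for a in pair.subA.members for b in pair.subB.members
        )
        assert count_connections(pair, m) == manual


class TestMutation:
    def test_spatial_offsets_bound_the_child(self, small_spaces):
        space_a, space_b = small_spaces
        cfg = toy_config(dx1=6.0, dy1=6.0, dz1=6.0)
        parent = Chromosome(
            *np.clip([10.0, 10.0, 10.0], space_a.bounds_lo, space_a.bounds_hi),
            int(space_a.lattice.values[2]),
            *space_b.bounds_lo, int(space_b.lattice.values[0]),
        )
        rng = np.random.default_rng(1)
        for _ in range(1000):
            child = mutate(parent, cfg, rng, space_a, space_b)
            assert parent.x1 - 6.0 - 1e-9 <= child.x1 <= parent.x1 + 6.0 + 1e-9
            assert np.all(np.asarray([child.x1, child.y1, child.z1]) >= space_a.bounds_lo - 1e-9)
            assert np.all(np.asarray([child.x1, child.y1, child.z1]) <= space_a.bounds_hi + 1e-9)
            assert np.all(np.asarray([child.x2, child.y2, child.z2]) >= space_b.bounds_lo - 1e-9)
            assert np.all(np.asarray([child.x2, child.y2, child.z2]) <= space_b.bounds_hi + 1e-9)
            assert child.l1 in space_a.lattice.values
            assert child.l2 in space_b.lattice.values

    def test_zero_offsets_are_identity_on_decoded_pair(self, small_spaces):
        from plastec.encoding import decode_chromosome

        space_a, space_b = small_spaces
        cfg = toy_config(dx1=0, dy1=0, dz1=0, dx2=0, dy2=0, dz2=0, dl1=0, dl2=0)
        parent = Chromosome(*space_a.centers[7], 3, *space_b.centers[9], 5)
        child = mutate(parent, cfg, np.random.default_rng(2), space_a, space_b)
        p = decode_chromosome(parent, space_a, space_b)
        c = decode_chromosome(child, space_a, space_b)
        np.testing.assert_array_equal(p.subA.members, c.subA.members)
        np.testing.assert_array_equal(p.subB.members, c.subB.members)


class TestSelection:
    def test_sorting_and_stable_ties(self):
        pool = list(zip("abcdef", [5, 4, 3, 2, 1, 0]))
        assert select_population_elitist(pool, 3) == ["a", "b", "c"]
        tied = list(zip("abcdef", [1, 1, 1, 1, 1, 1]))
        assert select_population_elitist(tied, 3) == ["a", "b", "c"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(3)
        fitness = rng.random(40)
        pool = list(zip(range(40), fitness))
        kept = select_population_elitist(pool, 20)
        expected = sorted(fitness, reverse=True)[:20]
        assert sorted((fitness[i] for i in kept), reverse=True) == pytest.approx(expected)


class TestBonferroni:
    def test_correction_arithmetic(self):
        # p_raw 0.001 with m=10 -> 0.01, kept; p_raw 0.01 with m=10 -> 0.1, dropped
        z_small = float(special.erfcinv(0.001) * np.sqrt(2))
        z_large = float(special.erfcinv(0.01) * np.sqrt(2))
        srps = [fake_srp(0, 0) for _ in range(10)]
        for s in srps[1:]:
            s.Z = 0.0
        srps[0].Z = z_small
        kept = bonferroni_filter(list(srps), alpha=0.05)
        assert kept == [srps[0]]
        assert srps[0].p_corrected == pytest.approx(0.01, rel=1e-6)
        srps[0].Z = z_large
        assert bonferroni_filter(list(srps), alpha=0.05) == []
        assert srps[0].p_corrected == pytest.approx(0.1, rel=1e-6)

    def test_p_raw_matches_erfc_oracle(self):
        srp = fake_srp(100, 150)
        srp.Z = 5.270462766947299
        bonferroni_filter([srp], alpha=0.05)
        assert srp.p_raw == pytest.approx(float(special.erfc(srp.Z / np.sqrt(2))), rel=1e-9)


class TestSearchLevel:
    def test_identical_matrices_give_zero_fitness(self, small_spaces):
        space_a, space_b = small_spaces
        rng = np.random.default_rng(4)
        m = (rng.random((len(space_a.roi), len(space_b.roi))) < 0.2).astype(np.uint8)
        level = run_ec_level(m, m, space_a, space_b, toy_config(4), np.random.default_rng(4))
        assert level.best.fitness == 0.0

    def test_best_ever_trace_is_monotone(self, small_spaces):
        space_a, space_b = small_spaces
        rng = np.random.default_rng(5)
        m1 = (rng.random((len(space_a.roi), len(space_b.roi))) < 0.1).astype(np.uint8)
        m2 = (rng.random(m1.shape) < 0.3).astype(np.uint8)
        level = run_ec_level(m1, m2, space_a, space_b, toy_config(5), np.random.default_rng(5))
        trace = np.array(level.best_fitness_trace)
        assert (np.diff(trace) >= 0).all()
        assert level.best.fitness == trace[-1]


class TestDetection:
    def test_planted_block_is_recovered(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            grid, roi_a, roi_b = make_geometry((8, 8, 8), (40, 50), rng)
            sa = ROISearchSpace(roi_a, grid, l_min=1, l_step=1)
            sb = ROISearchSpace(roi_b, grid, l_min=1, l_step=1)
            am, bm = plant_block(sa, sb, 15, 20, rng)
            truth = PlantedTruth(
                blocks=[PlantedBlock(a_members=am, b_members=bm, density1=0.0, density2=1.0)],
                background_density=0.0,
            )
            m1, m2 = make_matrix_dataset(truth, roi_a, roi_b, rng)
            res = detect_all_srps(m1, m2, sa, sb, toy_config(100 + seed))
            scores = [
                dice(tagged_voxel_set(s), truth_tagged_set(truth.blocks[0]))
                for s in res.srps
            ]
            if scores and max(scores) >= 0.6:
                assert res.srps[int(np.argmax(scores))].sign == 1
                hits += 1
        assert hits >= 4

    def test_two_disjoint_blocks_gain_and_loss(self):
        # recovering each block *exactly* (no split remainders) needs a more
        # thorough search than mere localisation; a larger population with
        # several offspring per parent provides it
        found = 0
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            grid, roi_a, roi_b = make_geometry((8, 8, 8), (40, 50), rng)
            sa = ROISearchSpace(roi_a, grid, l_min=1, l_step=1)
            sb = ROISearchSpace(roi_b, grid, l_min=1, l_step=1)
            am1, bm1 = plant_block(sa, sb, 8, 10, rng)
            am2, bm2 = plant_block(sa, sb, 8, 10, rng, avoid_a=set(am1.tolist()))
            truth = PlantedTruth(
                blocks=[
                    PlantedBlock(a_members=am1, b_members=bm1, density1=0.0, density2=1.0),
                    PlantedBlock(a_members=am2, b_members=bm2, density1=1.0, density2=0.0),
                ],
                background_density=0.0,
            )
            m1, m2 = make_matrix_dataset(truth, roi_a, roi_b, rng)
            cfg = toy_config(
                200 + seed, population_size=200, stall_generations=60,
                offspring_per_parent=3,
            )
            res = detect_all_srps(m1, m2, sa, sb, cfg)
            if sorted(s.sign for s in res.srps) == [-1, 1]:
                found += 1
        assert found >= 4

    def test_blocked_edges_are_disjoint_and_zeroed(self, small_spaces):
        space_a, space_b = small_spaces
        rng = np.random.default_rng(6)
        m1 = (rng.random((len(space_a.roi), len(space_b.roi))) < 0.05).astype(np.uint8)
        m2 = m1.copy()
        m2[:10, :12] = 1  # strong planted gain
        res = detect_all_srps(m1, m2, space_a, space_b, toy_config(6))
        assert len(res.detected) >= 1
        # replay the blocking in detection order: each recorded pair's counts
        # must come from edges no earlier pair consumed (disjoint support),
        # and its cells must be zero afterwards
        w1, w2 = m1.copy(), m2.copy()
        total_change = 0
        for srp in res.detected:
            assert count_connections(srp, w1) == srp.NC1
            assert count_connections(srp, w2) == srp.NC2
            total_change += abs(srp.NC2 - srp.NC1)
            block = np.ix_(srp.subA.members, srp.subB.members)
            w1[block] = 0
            w2[block] = 0
        for srp in res.detected:
            assert count_connections(srp, w1) == 0
            assert count_connections(srp, w2) == 0
        assert total_change <= m1.size

    def test_fixed_seed_reproduces_bitwise(self, small_spaces):
        space_a, space_b = small_spaces
        rng = np.random.default_rng(7)
        m1 = (rng.random((len(space_a.roi), len(space_b.roi))) < 0.1).astype(np.uint8)
        m2 = (rng.random(m1.shape) < 0.25).astype(np.uint8)
        r1 = detect_all_srps(m1, m2, space_a, space_b, toy_config(7))
        r2 = detect_all_srps(m1, m2, space_a, space_b, toy_config(7))
        assert len(r1.detected) == len(r2.detected)
        for a, b in zip(r1.detected, r2.detected):
            np.testing.assert_array_equal(a.subA.members, b.subA.members)
            np.testing.assert_array_equal(a.subB.members, b.subB.members)
            assert (a.NC1, a.NC2, a.Z) == (b.NC1, b.NC2, b.Z)
        assert [lv.best_fitness_trace for lv in r1.levels] == [
            lv.best_fitness_trace for lv in r2.levels
        ]

    def test_never_beats_exhaustive_enumeration(self):
        # tiny ROIs where every decodable pair can be enumerated
        for seed in range(2):
            rng = np.random.default_rng(80 + seed)
            grid, roi_a, roi_b = make_geometry((4, 4, 3), (8, 9), rng)
            sa = ROISearchSpace(roi_a, grid, l_min=1, l_step=1)
            sb = ROISearchSpace(roi_b, grid, l_min=1, l_step=1)
            m1 = (rng.random((8, 9)) < 0.3).astype(np.uint8)
            m2 = (rng.random((8, 9)) < 0.5).astype(np.uint8)
            sets_a, sets_b = enumerate_decoded_pairs(sa, sb)
            target = brute_force_max_fitness(sets_a, sets_b, m1, m2)
            n_pairs = len(sets_a) * len(sets_b)
            pop = n_pairs + (n_pairs % 2)
            cfg = ECConfig(
                population_size=pop, stall_generations=10, l_min=1, l_step=1,
                rng_seed=80 + seed,
            )
            level = run_ec_level(m1, m2, sa, sb, cfg, np.random.default_rng(80 + seed))
            assert level.best.fitness <= target + 1e-9

    def test_max_recursion_caps_levels(self, small_spaces):
        space_a, space_b = small_spaces
        m1 = np.zeros((len(space_a.roi), len(space_b.roi)), dtype=np.uint8)
        m2 = np.ones_like(m1)
        cfg = toy_config(9, max_recursion=2)
        res = detect_all_srps(m1, m2, space_a, space_b, cfg)
        assert len(res.detected) <= 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ECConfig(population_size=3)
        with pytest.raises(ValueError):
            ECConfig(dx1=-1.0)
        with pytest.raises(ValueError):
            ECConfig(offspring_per_parent=0)


def test_fitness_matches_oracle_on_random_triples(rng):
    for _ in range(200):
        tc = int(rng.integers(1, 500))
        nc1 = int(rng.integers(0, tc + 1))
        nc2 = int(rng.integers(0, tc + 1))
        _, fit, _, _ = fitness_zscore(nc1, nc2, tc)
        assert fit == pytest.approx(fitness_oracle(nc1, nc2, tc), rel=1e-9, abs=1e-12)
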