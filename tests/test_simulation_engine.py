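import numpy as np
import pandas as pd
import pytest

from pohsim import (
    SimulationCondition,
    SyntheticBaseSpec,
    parse_condition,
    run_generation,
    run_linked_simulation,
    run_replicates,
    run_simulation,
    select_pairs,
)


class TestParseCondition:
    @pytest.mark.parametrize(
        "tag, expected",
        [
            ("M51-BP10-Li4-Ge50", (51, 10, 4, 50)),
            ("M1-BP3-Li4-Ge50", (1, 3, 4, 50)),
        ],
    )
    def test_valid_tags(self, tag, expected):
        cond = parse_condition(tag)
        assert (cond.m, cond.bp, cond.li, cond.ge) == expected
        assert cond.tag == tag

    def test_malformed_tag_names_failing_field(self):
        with pytest.raises(ValueError, match="BP"):
            parse_condition("M51-BPx-Li4-Ge50")
        with pytest.raises(ValueError, match="Ge"):
            parse_condition("M51-BP10-Li4")


class TestRunGeneration:
    def test_population_size_is_bp_times_li(self, rng):
        base = __import__("pohsim").synthesize_base(SyntheticBaseSpec(seed=0))
        cond = SimulationCondition(m=51, bp=10, li=4, ge=1)
        nxt, stats = run_generation(base, cond, rng)
        assert nxt.n_individuals == 40
        assert nxt.generation_index == 1
        assert nxt.males.size == 20 and nxt.females.size == 20
        assert len(set(nxt.litter_id)) == 10

    def test_forced_heterozygote_generation(self, pop_factory, rng):
        pop = pop_factory([[0], [2]], "MF")
        cond = SimulationCondition(m=1, bp=1, li=4, ge=1)
        nxt, stats = run_generation(pop, cond, rng)
        assert stats.h_obs == 1.0
        assert stats.mean_pair_poh == 1.0

    def test_all_heterozygote_generation_caps_pair_score(self, pop_factory, rng):
        pop = pop_factory(np.ones((8, 1), dtype=np.int8), "MMMMFFFF")
        out = select_pairs(pop, 3, "POH", rng)
        assert out.mean_pair_score == 0.5
        assert max(p.score for p in out.pairs) == 0.5


class TestRunSimulation:
    def test_trajectory_includes_generation_zero(self, pop_factory):
        pop = pop_factory([[0], [1], [2], [1]], "MMFF")
        cond = SimulationCondition(m=1, bp=2, li=4, ge=5, seed=3)
        traj, truncated = run_simulation(pop, cond)
        assert not truncated
        assert traj["generation"].tolist() == list(range(6))
        assert np.isnan(traj.loc[0, "mean_pair_poh"])  # base has no breeders
        assert traj.loc[0, "h_obs"] == 0.5

    def test_identical_seeds_identical_trajectories(self, pop_factory):
        pop = pop_factory(np.random.default_rng(1).integers(0, 3, (10, 3)), "MMMMMFFFFF")
        cond = SimulationCondition(m=3, bp=3, li=4, ge=10, seed=11)
        t1, _ = run_simulation(pop, cond)
        t2, _ = run_simulation(pop, cond)
        pd.testing.assert_frame_equal(t1, t2)

    def test_fixation_is_not_an_error(self, pop_factory):
        # monomorphic base: all scores tie at 0 and heterozygosity stays 0
        pop = pop_factory(np.zeros((8, 2), dtype=np.int8), "MMMMFFFF")
        cond = SimulationCondition(m=2, bp=3, li=4, ge=8, seed=5)
        traj, truncated = run_simulation(pop, cond)
        assert not truncated
        assert (traj["h_obs"] == 0).all()
        assert (traj.loc[1:, "mean_pair_poh"] == 0).all()

    def test_single_pair_truncates_when_only_littermates_remain(self, pop_factory):
        # BP=1 produces a single litter, whose members are all littermates:
        # generation 2 is infeasible and the trajectory is truncated
        pop = pop_factory([[0], [2]], "MF")
        cond = SimulationCondition(m=1, bp=1, li=4, ge=10, seed=0)
        traj, truncated = run_simulation(pop, cond)
        assert truncated
        assert traj["generation"].tolist() == [0, 1]

    def test_single_marker_oscillation(self, pop_factory):
        # with one marker, reaching 100% heterozygosity forces AB x AB
        # matings (pair POH 0.5) and a fall-back the following generation
        base = __import__("pohsim").synthesize_base(
            SyntheticBaseSpec(n_males=6, n_females=6, n_loci=1, seed=4)
        )
        cond = SimulationCondition(m=1, bp=3, li=4, ge=50, seed=4)
        traj, _ = run_simulation(base, cond)
        peaks = traj.index[(traj["h_obs"] == 1.0) & (traj["generation"] < cond.ge)]
        assert len(peaks) > 0
        for t in peaks:
            assert traj.loc[t + 1, "mean_pair_poh"] == 0.5
            assert traj.loc[t + 1, "h_obs"] < 1.0


class TestRunReplicates:
    def test_single_run_aggregate_equals_trajectory(self, pop_factory):
        pop = pop_factory(np.random.default_rng(2).integers(0, 3, (10, 3)), "MMMMMFFFFF")
        cond = SimulationCondition(m=3, bp=3, li=4, ge=6, seed=9)
        res = run_replicates(pop, cond, 1)
        single, _ = run_simulation(pop, cond, np.random.default_rng(cond.seed))
        assert np.allclose(
            res.aggregate[["h_obs", "h_exp"]].to_numpy(),
            single[["h_obs", "h_exp"]].to_numpy(),
        )

    def test_aggregate_is_mean_of_replicates(self):
        cond = SimulationCondition(m=5, bp=3, li=4, ge=5, seed=2)
        res = run_replicates(SyntheticBaseSpec(n_loci=5, seed=2), cond, 4)
        assert res.n_replicates == 4
        recomputed = (
            res.replicates.groupby("generation")["h_obs"].mean().to_numpy()
        )
        assert np.allclose(res.aggregate["h_obs"].to_numpy(), recomputed)

    def test_replicates_differ(self):
        cond = SimulationCondition(m=5, bp=3, li=4, ge=5, seed=2)
        res = run_replicates(SyntheticBaseSpec(n_loci=5, seed=2), cond, 3)
        finals = res.replicates.groupby("replicate")["h_obs"].last()
        assert finals.nunique() > 1


class TestLinkedSimulation:
    def test_requires_single_scored_marker(self):
        with pytest.raises(ValueError, match="M = 1"):
            run_linked_simulation(np.array([0.1]), parse_condition("M2-BP3-Li4-Ge5"))

    def test_r_domain(self):
        with pytest.raises(ValueError):
            run_linked_simulation(np.array([0.7]), parse_condition("M1-BP3-Li4-Ge5"))

    def test_output_shape_and_determinism(self):
        r = np.array([0.1, 0.3])
        cond = parse_condition("M1-BP3-Li4-Ge20", seed=6)
        spec = SyntheticBaseSpec(n_loci=3, seed=6)
        a = run_linked_simulation(r, cond, base_spec=spec)
        b = run_linked_simulation(r, cond, base_spec=spec)
        assert a.shape == (21, 4)  # generations 0..20, generation + 3 locus columns
        pd.testing.assert_frame_equal(a, b)

    def test_complete_linkage_keeps_focal_association(self):
        # with r = 0 each gamete is a full parental haplotype, so every
        # offspring allele combination descends from a founder haplotype
        cond = parse_condition("M1-BP3-Li4-Ge100", seed=8)
        traj = run_linked_simulation(
            np.zeros(3), cond, base_spec=SyntheticBaseSpec(n_loci=4, seed=8)
        )
        assert ((traj.iloc[:, 1:] >= 0) & (traj.iloc[:, 1:] <= 1)).all().all()
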