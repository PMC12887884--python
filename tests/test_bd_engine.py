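"""BD propagation: step formula, diffusion statistics, reaction criterion,
ensemble bookkeeping, NAM rate."""

import numpy as np
import pytest

import gagbind as g
from gagbind.bd_engine import (BDParams, ReferenceAtomSets, bd_step,
                               check_reaction, nam_rate, run_ensemble,
                               run_trajectory)
from gagbind.geometry import Pose


@pytest.fixture
def params():
    return BDParams()


class TestBdStep:
    def test_zero_field_displacement_is_recorded_noise(self, params):
        seed = 123
        rng = np.random.default_rng(seed)
        pose = bd_step(Pose(), params, np.zeros(3), np.zeros(3), 1.0, rng)
        replay = np.random.default_rng(seed)
        xi_t = replay.standard_normal(3)
        expected = np.sqrt(2 * params.d_translation * 1.0) * xi_t
        assert np.array_equal(pose.translation, expected)

    def test_drift_along_constant_force(self, params):
        rng = np.random.default_rng(0)
        force = np.array([50.0, 0.0, 0.0])
        disp = np.mean([
            bd_step(Pose(), params, force, np.zeros(3), 1.0, rng).translation
            for _ in range(2000)], axis=0)
        drift = params.d_translation / params.kbt * 50.0
        assert disp[0] == pytest.approx(drift, rel=0.15)

    def test_nonfinite_force_aborts(self, params):
        with pytest.raises(FloatingPointError):
            bd_step(Pose(), params, np.array([np.nan, 0, 0]), np.zeros(3),
                    1.0, np.random.default_rng(0))

    def test_field_free_msd_slope_is_6Dt(self, params):
        # 100 replicas x 1000 field-free steps; MSD at t = 6 D t within 3 SE
        n_rep, n_steps, dt = 100, 1000, 1.0
        zero = np.zeros(3)
        final2 = np.empty(n_rep)
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            pose = Pose()
            for _ in range(n_steps):
                pose = bd_step(pose, params, zero, zero, dt, rng)
            final2[rep] = np.dot(pose.translation, pose.translation)
        expected = 6 * params.d_translation * n_steps * dt
        se = final2.std(ddof=1) / np.sqrt(n_rep)
        assert abs(final2.mean() - expected) < 3 * se

    def test_rotational_decorrelation(self, params):
        # <u(0)·u(t)> = exp(-2 D_r t) within 3 SE at two checkpoints
        n_rep, dt = 150, 1.0
        checkpoints = [400, 1000]
        zero = np.zeros(3)
        u0 = np.array([0.0, 0.0, 1.0])
        dots = {t: [] for t in checkpoints}
        for rep in range(n_rep):
            rng = np.random.default_rng(20_000 + rep)
            pose = Pose()
            for step in range(1, max(checkpoints) + 1):
                pose = bd_step(pose, params, zero, zero, dt, rng)
                if step in checkpoints:
                    dots[step].append(float(pose.rotation @ u0 @ u0))
        for t in checkpoints:
            vals = np.array(dots[t])
            expected = np.exp(-2 * params.d_rotation * t * dt)
            se = vals.std(ddof=1) / np.sqrt(n_rep)
            assert abs(vals.mean() - expected) < 3 * se


class TestReactionCriterion:
    def _refs(self, fibril, glycan):
        return ReferenceAtomSets.from_models(fibril, glycan)

    def test_far_pose_no_reaction(self, two_ladder_fibril, octasaccharide):
        refs = self._refs(two_ladder_fibril, octasaccharide)
        pose = Pose(np.eye(3), two_ladder_fibril.centroid + [0, 500.0, 0])
        assert check_reaction(pose, refs, BDParams()) is None

    def test_three_contacts_at_74_react_on_lys_ladder(self):
        fib = g.build_fibril(g.build_cross_section("K"), 6)
        gly = g.build_glycan(8)
        refs = ReferenceAtomSets.from_models(fib, gly)
        # place the glycan axis along the ladder, sulfurs 7.4 Å from NZ line
        nz = refs.fibril_refs
        target = nz.mean(axis=0) + np.array([0.0, 7.4, 0.0])
        rot = np.array([[0.0, 0, 1], [0, 1, 0], [-1, 0, 0]])  # x -> z
        body_c = gly.ring_centroids.mean(axis=0)
        pose = Pose(rot, target - rot @ body_c)
        world = pose.apply(refs.glycan_refs)
        d = np.linalg.norm(world[:, None] - nz[None], axis=2)
        assert (d <= 7.5).sum() >= 3          # constructed geometry holds
        assert check_reaction(pose, refs, BDParams()) == 1

    def test_two_contacts_insufficient(self):
        # synthetic refs: exactly 2 pairs within threshold
        refs = ReferenceAtomSets(
            glycan_refs=np.array([[0.0, 0, 0], [0, 0, 100.0]]),
            fibril_refs=np.array([[5.0, 0, 0], [0, 5.0, 0], [0, 0, 200.0]]),
            fibril_res_numbers=np.array([11, 11, 12]))
        assert check_reaction(Pose(), refs, BDParams()) is None
        # tightening the requirement to 2 flips the answer
        assert check_reaction(Pose(), refs,
                              BDParams(reaction_min_contacts=2)) == 11

    def test_tie_breaks_to_lowest_residue(self):
        refs = ReferenceAtomSets(
            glycan_refs=np.array([[0.0, 0, 0], [10.0, 0, 0], [5.0, 0, 0]]),
            fibril_refs=np.array([[0.0, 3, 0], [10.0, 3, 0]]),
            fibril_res_numbers=np.array([42, 17]))
        # one pair each for residues 42 and 17, plus middle sulfur reaching
        # neither: boundary-inclusive distances give a 1-1 tie at 2 contacts
        assert check_reaction(Pose(), refs,
                              BDParams(reaction_min_contacts=2)) == 17

    def test_matches_brute_force_oracle_on_random_poses(
            self, two_ladder_fibril, octasaccharide):
        refs = self._refs(two_ladder_fibril, octasaccharide)
        params = BDParams()
        rng = np.random.default_rng(5)
        from conftest import random_pose_near
        for _ in range(100):
            pose = random_pose_near(two_ladder_fibril, rng)
            world = pose.apply(refs.glycan_refs)
            # O(N*M) oracle
            pairs = [(i, j)
                     for i in range(len(world))
                     for j in range(len(refs.fibril_refs))
                     if np.linalg.norm(world[i] - refs.fibril_refs[j])
                     <= params.reaction_distance]
            if len(pairs) < params.reaction_min_contacts:
                expected = None
            else:
                counts = {}
                for _, j in pairs:
                    r = int(refs.fibril_res_numbers[j])
                    counts[r] = counts.get(r, 0) + 1
                best = max(counts.values())
                expected = min(r for r, c in counts.items() if c == best)
            assert check_reaction(pose, refs, params) == expected


class TestTrajectoriesAndEnsemble:
    def test_zero_max_steps_reports_immediately(self, two_ladder_fibril,
                                                octasaccharide):
        p = BDParams(max_steps=0)
        out = run_trajectory(two_ladder_fibril, octasaccharide, p,
                             np.random.default_rng(0))
        assert out.status == "max_steps" and out.n_steps == 0

    def test_free_diffusion_mostly_escapes(self):
        # zero charges, q barely above b: nearly every trajectory escapes
        fib = g.build_fibril(g.build_cross_section("K"), 3)
        fib.charges = np.zeros_like(fib.charges)
        gly = g.build_glycan(4)
        # uniform timestep: the near-shell refinement is irrelevant with no
        # field and only slows the walk
        p = BDParams(dt_near=1.0, b_radius=30.0, q_radius=33.0,
                     max_steps=30_000, seed=3)
        outs = run_ensemble([fib], [gly], 40, p)
        frac_esc = sum(o.status == "escaped" for o in outs) / len(outs)
        assert frac_esc > 0.9

    def test_ensemble_count_and_determinism(self, two_ladder_fibril):
        gly = g.build_glycan(4)
        p = BDParams(b_radius=40.0, q_radius=60.0, max_steps=60, seed=9)
        outs1 = run_ensemble([two_ladder_fibril] * 2, [gly] * 3, 5, p)
        outs2 = run_ensemble([two_ladder_fibril] * 2, [gly] * 3, 5, p)
        assert len(outs1) == 2 * 3 * 5
        for a, b in zip(outs1, outs2):
            assert (a.status, a.site, a.n_steps, a.stream_id) == \
                (b.status, b.site, b.n_steps, b.stream_id)
            assert np.array_equal(a.final_pose.translation,
                                  b.final_pose.translation)

    def test_batching_does_not_change_outcomes(self, two_ladder_fibril):
        gly = g.build_glycan(4)
        p = BDParams(b_radius=40.0, q_radius=60.0, max_steps=60, seed=9)
        big = run_ensemble([two_ladder_fibril], [gly], 7, p, batch_size=7)
        small = run_ensemble([two_ladder_fibril], [gly], 7, p, batch_size=2)
        for a, b in zip(big, small):
            assert (a.status, a.site, a.n_steps) == (b.status, b.site,
                                                     b.n_steps)
            assert np.array_equal(a.final_pose.translation,
                                  b.final_pose.translation)

    def test_single_trajectory_matches_ensemble_stream(self,
                                                       two_ladder_fibril):
        gly = g.build_glycan(4)
        p = BDParams(b_radius=40.0, q_radius=60.0, max_steps=60, seed=9)
        sid = (9, 0, 0, 2)
        solo = run_trajectory(two_ladder_fibril, gly, p,
                              np.random.default_rng(np.random.SeedSequence(sid)),
                              stream_id=sid)
        ens = run_ensemble([two_ladder_fibril], [gly], 3, p)[2]
        assert (solo.status, solo.site, solo.n_steps) == \
            (ens.status, ens.site, ens.n_steps)
        assert np.array_equal(solo.final_pose.translation,
                              ens.final_pose.translation)


class TestNamRate:
    def test_limits(self):
        d = 0.04
        assert nam_rate(0.0, 50, 500, d) == 0.0
        assert nam_rate(1.0, 50, 500, d) == pytest.approx(
            4 * np.pi * d * 50)

    def test_half_bound_large_q_is_half_kd(self):
        d = 0.04
        k = nam_rate(0.5, 50, 5e6, d)
        assert k == pytest.approx(0.5 * 4 * np.pi * d * 50, rel=1e-4)

    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError):
            nam_rate(0.5, 50, 50, 0.04)
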