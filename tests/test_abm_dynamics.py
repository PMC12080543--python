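"""Stochastic update engine: sampling, stepping, running, absorption."""

import collections

import numpy as np
import pytest
from scipy.stats import chisquare

from egosign.signed_graph import GeneratorSpec, SignedDigraph, generate
from egosign.abm_dynamics import (ModelParams, Schedule,
                                  estimate_paradise_probability,
                                  has_unstable_triad, prune_nontriadic_links,
                                  run, sample_ego_triad, step)
from egosign.mean_field import quasistationary_roots
from egosign.triad_logic import TriadClass, census


def single_triad_graph(s_ab, s_ac, s_bc):
    """Graph whose only ego-triad is (0; 1, 2) with the given signs."""
    return SignedDigraph(3, src=[0, 0, 1], dst=[1, 2, 2],
                         sign=[s_ab, s_ac, s_bc])


class TestSampling:
    def test_complete_k3_uniform_over_six_triads(self, rng):
        g = generate(GeneratorSpec("complete", 3, 0.5, seed=0))
        counts = collections.Counter()
        for _ in range(6000):
            t = sample_ego_triad(g, rng)
            counts[(t.focal, t.left, t.right)] += 1
        assert len(counts) == 6
        _, p = chisquare(list(counts.values()))
        assert p > 1e-3

    def test_single_inner_direction_always_used(self, rng):
        g = single_triad_graph(1, -1, 1)
        for _ in range(50):
            t = sample_ego_triad(g, rng, mode="general")
            assert (t.focal, t.left, t.right) == (0, 1, 2)
            assert t.signs == (1, -1, 1)

    def test_low_outdegree_node_never_focal(self, rng, hand_graph):
        # nodes 1 and 2 have a single out-link each
        for _ in range(100):
            assert sample_ego_triad(hand_graph, rng, mode="general").focal == 0

    def test_no_triads_raises(self, rng):
        g = SignedDigraph(3, src=[0, 1], dst=[1, 2], sign=[1, 1])
        with pytest.raises(ValueError, match="no ego-based triads"):
            sample_ego_triad(g, rng, mode="general")


class TestPrune:
    def test_complete_graph_unchanged(self):
        g = generate(GeneratorSpec("complete", 6, 0.5, seed=1))
        assert prune_nontriadic_links(g).num_edges == g.num_edges

    def test_dangling_edge_removed(self, triangle_plus_dangling):
        pruned = prune_nontriadic_links(triangle_plus_dangling)
        assert pruned.num_edges == 3
        assert not pruned.has_edge(3, 0)

    def test_triadless_graph_empties(self):
        g = SignedDigraph(4, src=[0, 1, 2], dst=[1, 2, 3], sign=[1, 1, 1])
        assert prune_nontriadic_links(g).num_edges == 0

    def test_matches_exhaustive_membership(self, rng):
        g = generate(GeneratorSpec("random_directed", 12, 0.5, seed=4,
                                   edge_prob=0.25))
        pruned = prune_nontriadic_links(g)
        kept = set(zip(pruned.src.tolist(), pruned.dst.tolist()))
        # brute force: an edge is kept iff some ego-triad uses it
        expected = set()
        n = g.num_nodes
        for a in range(n):
            for b in range(n):
                for c in range(n):
                    if len({a, b, c}) < 3:
                        continue
                    if g.has_edge(a, b) and g.has_edge(a, c) \
                            and g.has_edge(b, c):
                        expected |= {(a, b), (a, c), (b, c)}
        assert kept == expected


class TestStep:
    def test_bn1_status_flips_negative_to_uh0(self, rng):
        # status-unstable BN1 with p_st = 1 repairs into UH0
        g = single_triad_graph(-1, 1, -1)
        rec = step(g, ModelParams(q=1.0, p_sbt=0.5, p_st=1.0), rng,
                   mode="general")
        assert rec.unstable and rec.theory == "status"
        assert (g.sign_of(0, 1), g.sign_of(0, 2), g.sign_of(1, 2)) == (1, 1, -1)

    def test_uh2_balance_always_flips_a_negative(self, rng):
        for psbt in (0.0, 0.5, 1.0):
            for _ in range(10):
                g = single_triad_graph(-1, -1, -1)
                rec = step(g, ModelParams(q=0.0, p_sbt=psbt, p_st=0.5), rng,
                           mode="general")
                assert rec.unstable
                # exactly one focal link became positive; inner untouched
                assert sorted([g.sign_of(0, 1), g.sign_of(0, 2)]) == [-1, 1]
                assert g.sign_of(1, 2) == -1

    def test_bh0_stable_under_both_theories(self, rng):
        for q in (0.0, 1.0):
            g = single_triad_graph(1, 1, 1)
            rec = step(g, ModelParams(q=q, p_sbt=0.1, p_st=0.9), rng,
                       mode="general")
            assert not rec.unstable and rec.flipped is None

    def test_inner_link_never_changed(self, rng):
        params = ModelParams(q=0.5, p_sbt=0.3, p_st=0.7)
        g = generate(GeneratorSpec("complete", 5, 0.5, seed=2))
        for _ in range(200):
            before = g.sign.copy()
            rec = step(g, params, rng)
            changed = np.nonzero(before != g.sign)[0]
            if rec.flipped is None:
                assert changed.size == 0
            else:
                assert changed.size == 1
                u, v = rec.flipped
                assert u == rec.triad.focal and v in (rec.triad.left,
                                                      rec.triad.right)


class TestRun:
    def test_paradise_immediately_absorbing(self):
        g = generate(GeneratorSpec("complete", 20, 1.0, seed=0))
        res = run(g, ModelParams(0.5, 0.5, 0.5), rng=1)
        assert res.absorbed == "paradise"
        assert res.quasistationary_rho == 1.0
        assert res.steps_run == 0

    def test_supercritical_sbt_reaches_paradise(self):
        # q=0, p_sbt=0.9 lies above the 0.75 critical point
        g = generate(GeneratorSpec("complete", 100, 0.5, seed=3))
        res = run(g, ModelParams(0.0, 0.9, 0.5), rng=4)
        assert res.absorbed == "paradise"
        assert res.rho_trajectory[-1] == 1.0

    def test_symmetric_point_stays_at_half(self):
        g = generate(GeneratorSpec("complete", 100, 0.5, seed=5))
        res = run(g, ModelParams(0.5, 0.5, 0.5), rng=6)
        assert res.absorbed == "none"
        assert res.quasistationary_rho == pytest.approx(0.5, abs=0.02)

    def test_all_negative_not_absorbing_when_balance_active(self):
        g = generate(GeneratorSpec("complete", 30, 0.0, seed=7))
        res = run(g, ModelParams(0.5, 0.5, 0.5), rng=8,
                  schedule=Schedule(burnin_sweeps=1, window_sweeps=2))
        assert res.rho_trajectory[1] > 0.0

    def test_quasistationary_rho_independent_of_q_at_pst_half(self):
        # p_st = 0.5 makes the interior root q-free (here 0.4271 at p_sbt=0.3)
        root = quasistationary_roots(ModelParams(0.0, 0.3, 0.5)).interior_stable
        rhos = []
        for i, q in enumerate((0.1, 0.5, 0.9)):
            g = generate(GeneratorSpec("complete", 100, 0.5, seed=10 + i))
            res = run(g, ModelParams(q, 0.3, 0.5), rng=20 + i)
            rhos.append(res.quasistationary_rho)
            assert res.quasistationary_rho == pytest.approx(root, abs=0.02)
        assert max(rhos) - min(rhos) < 0.02

    def test_same_seed_replays_identically(self):
        g = generate(GeneratorSpec("complete", 30, 0.5, seed=9))
        r1 = run(g, ModelParams(0.4, 0.6, 0.3), rng=77)
        r2 = run(g, ModelParams(0.4, 0.6, 0.3), rng=77)
        assert np.array_equal(r1.rho_trajectory, r2.rho_trajectory)
        assert r1.steps_run == r2.steps_run

    def test_input_graph_not_mutated(self):
        g = generate(GeneratorSpec("complete", 20, 0.5, seed=11))
        before = g.sign.copy()
        run(g, ModelParams(0.5, 0.5, 0.5), rng=12,
            schedule=Schedule(burnin_sweeps=2, window_sweeps=2))
        assert np.array_equal(g.sign, before)

    def test_census_snapshots_recorded(self):
        g = generate(GeneratorSpec("complete", 30, 0.5, seed=13))
        res = run(g, ModelParams(0.0, 0.5, 0.5), rng=14,
                  schedule=Schedule(burnin_sweeps=5, window_sweeps=20,
                                    census_every=5))
        assert len(res.census_snapshots) >= 4
        assert res.census_snapshots[0].total == 30 * 29 * 28


class TestParadiseProbability:
    def test_rho0_one_always_paradise(self):
        pp, _ = estimate_paradise_probability(
            GeneratorSpec("complete", 20, 1.0), ModelParams(0.5, 0.5, 0.5),
            reps=3, rng=1)
        assert pp == 1.0

    def test_subcritical_never_escapes_at_n100(self):
        pp, _ = estimate_paradise_probability(
            GeneratorSpec("complete", 100, 0.5), ModelParams(0.0, 0.5, 0.5),
            reps=5, rng=2,
            schedule=Schedule(burnin_sweeps=20, window_sweeps=20))
        assert pp == 0.0

    def test_separatrix_splits_basins(self):
        # bistable portrait: stable 0.714, separatrix 0.833, paradise stable
        params = ModelParams(0.5, 0.92, 0.2)
        portrait = quasistationary_roots(params)
        assert portrait.regime == "bistable"
        # absorption from rho0=0.95 typically needs ~90 sweeps at N=100
        sched = Schedule(burnin_sweeps=150, window_sweeps=50)
        below, _ = estimate_paradise_probability(
            GeneratorSpec("complete", 100, 0.70), params, reps=8, rng=3,
            schedule=sched)
        above, _ = estimate_paradise_probability(
            GeneratorSpec("complete", 100, 0.95), params, reps=8, rng=4,
            schedule=sched)
        assert below <= 0.2
        assert above >= 0.8


def test_frozen_motif_detection():
    # UH1 triad plus reciprocal negative inner link, isolated: no focal
    # agent can ever repair it once the focal links agree with stability
    g = SignedDigraph(3, src=[0, 0, 1, 2], dst=[1, 2, 2, 1],
                      sign=[1, 1, 1, 1])
    assert not has_unstable_triad(g, ModelParams(0.5, 0.5, 0.5))
    g2 = SignedDigraph(3, src=[0, 0, 1], dst=[1, 2, 2], sign=[1, 1, -1])
    assert has_unstable_triad(g2, ModelParams(0.0, 0.5, 0.5))
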