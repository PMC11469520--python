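"""MDP contracts, Q-function symmetry, episodes and Q-learning."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from oracles import brute_force_proposals

from qpharm.errors import ContractError, InvalidActionError, QPharmError
from qpharm.features import FeatureClass, PharmFeature
from qpharm.protein import ProteinAtom, ProteinStructure
from qpharm.rl import (TERMINAL, EpsilonSchedule, PharmEnv,
                       PharmGraph, QNetwork, QTrainConfig, build_graph,
                       build_pharmacophore, epsilon_at, library_reward,
                       propose, q_value, run_episode, train_q,
                       value_iteration)


def _features(positions, rng=None, emb=32):
    rng = rng or np.random.default_rng(0)
    feats = []
    for i, p in enumerate(positions):
        feats.append(PharmFeature(p, FeatureClass(i % 6),
                                  confidence=0.5 + 0.05 * (i % 6),
                                  embedding=rng.normal(size=emb)))
    return feats


def _protein_near(positions, dist=3.0):
    atoms = [ProteinAtom(np.asarray(p) + [dist, 0, 0], "C", "GLY", "CA",
                         res_id=i + 1)
             for i, p in enumerate(positions)]
    return ProteinStructure(atoms, [])


# ------------------------------------------------------------- structure

def test_build_graph_edge_thresholds():
    feats = _features([[0, 0, 0], [6, 0, 0], [0, 9, 0]])
    protein = ProteinStructure(
        [ProteinAtom([0, 0, 4.9], "C", "GLY", "CA")], [])
    g = build_graph((0, 1), feats, protein)
    assert g.edges_ff == [(0, 1)]  # 6 Å <= delta_ff = 8
    g2 = build_graph((0, 2), feats, protein)
    assert g2.edges_ff == []  # 9 Å > 8: nodes co-exist without an edge
    assert g2.protein_nodes == [0]  # atom at 4.9 Å < delta_fp = 5
    assert (0, 0) in g2.edges_fp


def test_propose_matches_bruteforce_neighborhoods():
    rng = np.random.default_rng(21)
    for _ in range(100):
        n = int(rng.integers(4, 10))
        positions = rng.uniform(0, 14, size=(n, 3))
        feats = _features(positions, rng)
        protein = _protein_near(positions[:2])
        k = int(rng.integers(1, n))
        selected = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        state = build_graph(selected, feats, protein)
        prop = propose(state, feats, protein)
        assert set(prop.candidate_indices) == \
            brute_force_proposals(selected, positions, 8.0)
        assert prop.terminal_allowed == (len(selected) >= 3)


def test_terminal_gating_and_invalid_action():
    positions = [[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0]]
    feats = _features(positions)
    env = PharmEnv(feats, _protein_near(positions), lambda p: 1.0)
    g1 = env.reset(0)
    with pytest.raises(InvalidActionError):
        env.step(g1, TERMINAL)
    g3 = env.graph((0, 1, 2))
    tr = env.step(g3, TERMINAL)
    assert tr.done and tr.action_graph is g3 and tr.reward == 1.0


def test_reward_gated_below_min_features():
    positions = [[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0]]
    feats = _features(positions)
    env = PharmEnv(feats, _protein_near(positions), lambda p: 0.8)
    rng = np.random.default_rng(1)
    for _ in range(20):
        for tr in run_episode(env, None, epsilon=1.0, rng=rng):
            if tr.action_graph.n_features < 3:
                assert tr.reward == 0.0
            else:
                assert tr.reward == pytest.approx(0.8)


def test_min_features_four_mode():
    positions = [[0, 0, 0], [3, 0, 0], [0, 3, 0], [3, 3, 0], [1, 1, 3]]
    feats = _features(positions)
    protein = _protein_near(positions)
    prop3 = propose(build_graph((0, 1, 2), feats, protein), feats, protein,
                    min_features=4)
    assert not prop3.terminal_allowed
    prop4 = propose(build_graph((0, 1, 2, 3), feats, protein), feats, protein,
                    min_features=4)
    assert prop4.terminal_allowed


# ------------------------------------------------------------ ε-schedule

def test_epsilon_closed_form():
    s = EpsilonSchedule(eps0=0.9, epsT=0.1, alpha=100.0)
    assert epsilon_at(s, 0) == pytest.approx(0.9, abs=1e-12)
    assert epsilon_at(s, 1e9) == pytest.approx(0.1, abs=1e-12)
    assert epsilon_at(s, 100) == pytest.approx(0.1 + 0.8 * np.exp(-1.0),
                                               abs=1e-12)
    ts = np.linspace(0, 500, 100)
    vals = [epsilon_at(s, t) for t in ts]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


# ------------------------------------------------------------ Q-function

def test_q_invariance_under_rigid_motion_and_permutation():
    rng = np.random.default_rng(5)
    net = QNetwork(32, seed=2)
    for _ in range(25):
        n = int(rng.integers(3, 7))
        positions = rng.uniform(0, 10, size=(n, 3))
        feats = _features(positions, rng)
        protein = _protein_near(positions)
        g = build_graph(tuple(range(n)), feats, protein)
        q0 = net.q(g, protein)

        rot, dv = Rotation.random(rng=rng), rng.uniform(-20, 20, 3)
        feats2 = [PharmFeature(rot.apply(f.position) + dv, f.cls, f.radius,
                               None, f.confidence, f.embedding)
                  for f in feats]
        prot2 = ProteinStructure(
            [ProteinAtom(rot.apply(a.position) + dv, a.element,
                         a.residue_name, a.atom_name, res_id=a.res_id)
             for a in protein.atoms], [])
        g2 = build_graph(tuple(range(n)), feats2, prot2)
        assert abs(net.q(g2, prot2) - q0) <= 1e-4

        perm = rng.permutation(n).tolist()
        g3 = PharmGraph(
            g.feature_indices,
            [g.feature_nodes[p] for p in perm],
            list(g.protein_nodes),
            [(perm.index(i), perm.index(j)) for i, j in g.edges_ff],
            [(perm.index(i), p) for i, p in g.edges_fp])
        assert abs(net.q(g3, protein) - q0) <= 1e-6


def test_q_requires_embeddings():
    positions = [[0, 0, 0], [3, 0, 0], [0, 3, 0]]
    feats = [PharmFeature(p, FeatureClass.Aromatic if i else
                          FeatureClass.Hydrophobic)
             for i, p in enumerate(positions)]
    protein = _protein_near(positions)
    g = build_graph((0, 1, 2), feats, protein)
    with pytest.raises(ContractError):
        q_value(QNetwork(32), g, protein)


# -------------------------------------------------------------- episodes

def test_episode_determinism_and_length(unique_task):
    env = PharmEnv(unique_task.features, unique_task.protein,
                   library_reward(unique_task.library))
    net = QNetwork(32, seed=0)
    t1 = run_episode(env, net, 0.4, np.random.default_rng(33))
    t2 = run_episode(env, net, 0.4, np.random.default_rng(33))
    assert [tr.action_graph.feature_indices for tr in t1] == \
        [tr.action_graph.feature_indices for tr in t2]
    for _ in range(10):
        rng = np.random.default_rng(int(_))
        trs = run_episode(env, None, 1.0, rng)  # pure random walk
        assert len(trs) <= len(env.features) + 1


def test_environment_needs_enough_features():
    feats = _features([[0, 0, 0], [3, 0, 0]])
    with pytest.raises(QPharmError):
        PharmEnv(feats, _protein_near([[0, 0, 0]]), lambda p: 0.0)


# -------------------------------------------------------------- training

def test_gamma_zero_ranks_by_immediate_reward(unique_task):
    env = PharmEnv(unique_task.features, unique_task.protein,
                   library_reward(unique_task.library))
    cfg = QTrainConfig(episodes=120, ensemble_size=1, seed=2, gamma=0.0,
                       final_fit_sweeps=5)
    res = train_q(env, cfg)
    net = res.ensemble[0]
    qs, rs = [], []
    for key in res.visited[0]:
        g = env.graph(tuple(key))
        qs.append(net.q(g, env.protein))
        rs.append(env.reward(g))
    qs, rs = np.array(qs), np.array(rs)
    # at gamma = 0 the fixed point is Q = immediate reward
    assert np.max(np.abs(qs - rs)) < 0.1
    levels = np.unique(rs)
    level_means = [qs[rs == lv].mean() for lv in levels]
    rho = spearmanr(level_means, levels).statistic
    assert rho > 0.95


def test_default_ensemble_size_trains_five_members(unique_task):
    env = PharmEnv(unique_task.features, unique_task.protein,
                   library_reward(unique_task.library))
    assert QTrainConfig().ensemble_size == 5
    cfg = QTrainConfig(episodes=4, fit_every=2, fit_epochs=4,
                       final_fit_sweeps=0, seed=1)
    res = train_q(env, cfg)
    assert len(res.ensemble) == 5
    assert all(len(r) == 4 for r in res.episode_rewards)


def test_trained_policy_recovers_optimum(trained_policy):
    task, env, result = trained_policy
    net = result.ensemble[0]
    rng = np.random.default_rng(0)
    for seed_feature in task.optimal_indices:
        trs = run_episode(env, net, 0.0, rng, seed_feature=seed_feature)
        assert trs[-1].done
        assert trs[-1].action_graph.feature_indices == task.optimal_indices


def test_build_pharmacophore_ranked_output(trained_policy):
    task, env, result = trained_policy
    ranked = build_pharmacophore(result.ensemble * 5, task.features,
                                 task.protein,
                                 reward_fn=library_reward(task.library),
                                 top_k=2)
    assert 1 <= len(ranked) <= 10  # 5 members x 2 seeds, deduplicated
    top, score = ranked[0]
    assert score == pytest.approx(1.0)
    got = {tuple(np.round(f.position, 6)) for f in top.features}
    want = {tuple(np.round(task.features[i].position, 6))
            for i in task.optimal_indices}
    assert got == want


def test_build_pharmacophore_min_four(trained_policy):
    task, env, result = trained_policy
    ranked = build_pharmacophore(result.ensemble, task.features, task.protein,
                                 reward_fn=library_reward(task.library),
                                 min_features=4, top_k=3)
    assert all(len(p) >= 4 for p, _ in ranked)


def test_value_iteration_fixed_point_structure(unique_task):
    env = PharmEnv(unique_task.features, unique_task.protein,
                   library_reward(unique_task.library))
    gamma = 0.9
    qstar = value_iteration(env, gamma)
    opt = frozenset(unique_task.optimal_indices)
    # the optimum terminates: Q*(opt) = R + gamma * R with R = 1
    assert qstar[opt] == pytest.approx(1.0 + gamma)
    # its 2-subsets lead into it
    for drop in unique_task.optimal_indices:
        sub = opt - {drop}
        assert qstar[sub] == pytest.approx(gamma * (1.0 + gamma), abs=1e-6)
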