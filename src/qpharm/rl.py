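"""Pharmacophore assembly as a graph-building Markov decision process.

States are heterogeneous protein-pharmacophore graphs: feature nodes
(candidate interaction points with their latent embeddings), protein nodes
(heavy atoms near any feature node), feature-feature edges within
``delta_ff`` and feature-protein edges within ``delta_fp``.  An action
either grows the graph by one admissible feature (one within ``delta_ff``
of the current graph) or, once the graph has at least ``min_features``
nodes, terminates.  The reward of a graph is the F1 score its feature set
earns when screened against a labelled active/decoy library; graphs below
the minimum size earn 0.

The Q-function is a scalar-valued network over such graphs, invariant
under global rotation, translation and node reordering: geometry enters
only through interatomic distances, and node information is aggregated by
sum pooling.  Internally it is a fixed (untrained) random-feature
message-passing encoder producing a graph descriptor, followed by a
trainable MLP head fitted to temporal-difference targets
y = r + γ·max over next proposals (Q-learning with a replay buffer and a
periodically synchronized target copy).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import ContractError, InvalidActionError, QPharmError
from .features import N_CLASSES, PharmFeature, Pharmacophore
from .nn import MLP
from .protein import N_CHANNELS, ProteinStructure, atom_channel

TERMINAL = -1  # action index meaning "keep the current graph and stop"


@dataclass(frozen=True)
class GraphThresholds:
    delta_ff: float = 8.0  # feature-feature edge / candidate radius (Å)
    delta_fp: float = 5.0  # feature-protein edge radius (Å)

    def __post_init__(self):
        if self.delta_ff <= 0 or self.delta_fp <= 0:
            raise ValueError("distance thresholds must be positive")


@dataclass
class PharmGraph:
    """One MDP state: selected features plus their protein environment."""

    feature_indices: tuple[int, ...]  # indices into the full candidate set
    feature_nodes: list[PharmFeature]
    protein_nodes: list[int]  # heavy-atom indices into protein.atoms
    edges_ff: list[tuple[int, int]]  # local feature-node index pairs
    edges_fp: list[tuple[int, int]]  # (feature local idx, protein local idx)

    @property
    def n_features(self) -> int:
        return len(self.feature_nodes)

    @property
    def key(self) -> frozenset:
        return frozenset(self.feature_indices)

    def pharmacophore(self, name: str = "candidate") -> Pharmacophore:
        return Pharmacophore(list(self.feature_nodes), name)


@dataclass
class ProposalSet:
    current: PharmGraph
    candidates: list[PharmGraph]
    candidate_indices: list[int]  # feature index added by each candidate
    terminal_allowed: bool

    @property
    def dead_end(self) -> bool:
        return not self.candidates and not self.terminal_allowed


@dataclass
class Transition:
    state: PharmGraph
    action_graph: PharmGraph
    reward: float
    next_proposals: ProposalSet | None
    done: bool
    dead_end: bool = False


@dataclass
class EpsilonSchedule:
    """Exponential exploration decay: ε_t = ε_T + (ε_o − ε_T)·e^(−t/α)."""

    eps0: float = 0.9
    epsT: float = 0.1
    alpha: float = 100.0

    def __post_init__(self):
        if not 0.0 <= self.epsT <= self.eps0 <= 1.0:
            raise ValueError("require 0 <= epsT <= eps0 <= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


def epsilon_at(schedule: EpsilonSchedule, t: float) -> float:
    if t < 0:
        raise ValueError("t must be >= 0")
    return schedule.epsT + (schedule.eps0 - schedule.epsT) * np.exp(-t / schedule.alpha)


@dataclass
class QTrainConfig:
    gamma: float = 0.99
    min_features: int = 3
    target_sync_every: int = 100  # gradient updates between target syncs
    replay_capacity: int = 5000
    batch_size: int = 64
    learning_rate: float = 3e-3
    episodes: int = 300
    seed: int = 0
    ensemble_size: int = 5
    eps0: float = 0.9
    epsT: float = 0.1
    alpha: float | None = None  # default: episodes / 4
    fit_every: int = 5  # episodes between replay fits
    fit_epochs: int = 40
    final_fit_sweeps: int = 15  # fitted value-iteration sweeps after episodes
    hidden_size: int = 64

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.min_features < 3:
            raise ValueError("min_features must be >= 3")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")

    @property
    def schedule(self) -> EpsilonSchedule:
        alpha = self.alpha if self.alpha is not None else max(self.episodes / 4, 1)
        return EpsilonSchedule(self.eps0, self.epsT, alpha)


# ---------------------------------------------------------------------
# graph construction and proposals
# ---------------------------------------------------------------------

def build_graph(selected: Sequence[int], all_features: list[PharmFeature],
                protein: ProteinStructure,
                thresholds: GraphThresholds | None = None) -> PharmGraph:
    """Deterministically build the graph for a feature subset.

    Protein nodes are exactly the heavy atoms within ``delta_fp`` of any
    selected feature; edges follow the distance thresholds.
    """
    thresholds = thresholds or GraphThresholds()
    selected = tuple(sorted(selected))
    if not selected:
        raise ValueError("cannot build a graph from an empty feature subset")
    nodes = [all_features[i] for i in selected]
    pos = np.array([f.position for f in nodes])

    edges_ff = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if np.linalg.norm(pos[i] - pos[j]) <= thresholds.delta_ff:
                edges_ff.append((i, j))

    heavy_idx = [i for i, a in enumerate(protein.atoms) if not a.is_hydrogen]
    protein_nodes, edges_fp = [], []
    if heavy_idx:
        heavy_pos = np.array([protein.atoms[i].position for i in heavy_idx])
        d = np.linalg.norm(pos[:, None, :] - heavy_pos[None, :, :], axis=-1)
        near = np.nonzero((d <= thresholds.delta_fp).any(axis=0))[0]
        local = {int(a): loc for loc, a in enumerate(near)}
        protein_nodes = [heavy_idx[a] for a in near]
        for fi in range(len(nodes)):
            for a in near:
                if d[fi, a] <= thresholds.delta_fp:
                    edges_fp.append((fi, local[int(a)]))
    return PharmGraph(selected, nodes, protein_nodes, edges_ff, edges_fp)


def propose(state: PharmGraph, all_features: list[PharmFeature],
            protein: ProteinStructure,
            thresholds: GraphThresholds | None = None,
            min_features: int = 3) -> ProposalSet:
    """Candidate next graphs: one per admissible new feature (absent from
    the state, within ``delta_ff`` of some feature node).  Termination is
    allowed once the state has at least ``min_features`` nodes."""
    thresholds = thresholds or GraphThresholds()
    current_pos = np.array([f.position for f in state.feature_nodes])
    candidates, indices = [], []
    for i, feat in enumerate(all_features):
        if i in state.feature_indices:
            continue
        d = np.linalg.norm(current_pos - feat.position, axis=1)
        if np.any(d <= thresholds.delta_ff):
            candidates.append(build_graph(state.feature_indices + (i,),
                                          all_features, protein, thresholds))
            indices.append(i)
    return ProposalSet(state, candidates, indices,
                       terminal_allowed=state.n_features >= min_features)


# ---------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------

class PharmEnv:
    """MDP environment over one candidate feature set and reward oracle.

    ``reward_fn`` maps a Pharmacophore to its screening F1; it is only
    consulted for graphs with at least ``min_features`` nodes and its
    results are cached per feature subset.
    """

    def __init__(self, all_features: list[PharmFeature],
                 protein: ProteinStructure,
                 reward_fn: Callable[[Pharmacophore], float],
                 thresholds: GraphThresholds | None = None,
                 min_features: int = 3):
        if len(all_features) < min_features:
            raise QPharmError(
                f"environment needs at least {min_features} candidate features")
        self.features = all_features
        self.protein = protein
        self.reward_fn = reward_fn
        self.thresholds = thresholds or GraphThresholds()
        self.min_features = min_features
        self._reward_cache: dict[frozenset, float] = {}
        self._graph_cache: dict[frozenset, PharmGraph] = {}
        self._desc_cache: dict[frozenset, np.ndarray] = {}

    def descriptor(self, network: "QNetwork", graph: PharmGraph) -> np.ndarray:
        """Graph descriptor, cached per feature subset (the encoder is a
        fixed function of the subset's geometry, shared by all members)."""
        key = graph.key
        desc = self._desc_cache.get(key)
        if desc is None:
            desc = network.descriptor(graph, self.protein)
            self._desc_cache[key] = desc
        return desc

    def graph(self, selected: Sequence[int]) -> PharmGraph:
        key = frozenset(selected)
        if key not in self._graph_cache:
            self._graph_cache[key] = build_graph(selected, self.features,
                                                 self.protein, self.thresholds)
        return self._graph_cache[key]

    def reset(self, seed_feature: int) -> PharmGraph:
        return self.graph((seed_feature,))

    def proposals(self, state: PharmGraph) -> ProposalSet:
        return propose(state, self.features, self.protein, self.thresholds,
                       self.min_features)

    def reward(self, graph: PharmGraph) -> float:
        if graph.n_features < self.min_features:
            return 0.0
        key = graph.key
        if key not in self._reward_cache:
            self._reward_cache[key] = float(
                self.reward_fn(graph.pharmacophore()))
        return self._reward_cache[key]

    def step(self, state: PharmGraph, action: int,
             proposals: ProposalSet | None = None) -> Transition:
        """Apply an action: ``TERMINAL`` keeps the state and stops; any
        other value indexes a candidate graph."""
        proposals = proposals or self.proposals(state)
        if action == TERMINAL:
            if not proposals.terminal_allowed:
                raise InvalidActionError(
                    f"termination requires at least {self.min_features} "
                    f"feature nodes, state has {state.n_features}")
            action_graph = state
            done = True
        else:
            if not 0 <= action < len(proposals.candidates):
                raise InvalidActionError(f"no candidate with index {action}")
            action_graph = proposals.candidates[action]
            done = False
        reward = self.reward(action_graph)
        next_proposals = None if done else self.proposals(action_graph)
        return Transition(state, action_graph, reward, next_proposals, done)


def library_reward(library, options=None) -> Callable[[Pharmacophore], float]:
    """Reward oracle backed by the internal screener."""
    from .screening import screen_library

    def fn(pharm: Pharmacophore) -> float:
        return screen_library(pharm, library, options).metrics.f1

    return fn


# ---------------------------------------------------------------------
# Q-network
# ---------------------------------------------------------------------

class _GraphEncoder:
    """Fixed random-feature message-passing encoder over a graph.

    Geometry enters only as pairwise distances expanded in a Gaussian
    radial basis; node contributions are sum-pooled.  The encoder weights
    are drawn once from a fixed seed and never trained, so two networks
    with the same embedding size share descriptors exactly.
    """

    N_RBF = 8
    HIDDEN = 24
    OUT = 32
    _FIXED_SEED = 716253

    def __init__(self, embedding_size: int, delta_ff: float, delta_fp: float):
        self.embedding_size = embedding_size
        rng = np.random.default_rng(self._FIXED_SEED + 1000 * embedding_size)
        feat_dim = N_CLASSES + embedding_size
        h, k = self.HIDDEN, self.N_RBF
        s = 1.0
        self.A1 = rng.normal(0, s / np.sqrt(feat_dim), (feat_dim, h))
        self.A2 = rng.normal(0, s / np.sqrt(h + k), (h + k, h))
        self.A3 = rng.normal(0, s / np.sqrt(N_CHANNELS), (N_CHANNELS, h))
        self.A4 = rng.normal(0, s / np.sqrt(h + k), (h + k, h))
        self.A5 = rng.normal(0, s / np.sqrt(3 * h), (3 * h, self.OUT))
        self.centers_ff = np.linspace(0.0, delta_ff, k)
        self.centers_fp = np.linspace(0.0, delta_fp, k)
        self.rbf_gamma = 2.0
        self.dim = 2 * self.OUT + self.N_RBF + N_CLASSES + 4

    def _rbf(self, d: np.ndarray, centers: np.ndarray) -> np.ndarray:
        return np.exp(-self.rbf_gamma * (d[..., None] - centers) ** 2)

    def __call__(self, graph: PharmGraph, protein: ProteinStructure) -> np.ndarray:
        nf = graph.n_features
        attrs = np.zeros((nf, N_CLASSES + self.embedding_size))
        for i, f in enumerate(graph.feature_nodes):
            if f.embedding is None:
                raise ContractError(
                    "feature nodes must carry embeddings for the Q-function")
            if len(f.embedding) != self.embedding_size:
                raise ContractError(
                    f"embedding length {len(f.embedding)} != configured "
                    f"{self.embedding_size}")
            attrs[i, int(f.cls)] = 1.0
            attrs[i, N_CLASSES:] = f.embedding
        u = np.tanh(attrs @ self.A1)  # (nf, h)

        fpos = np.array([f.position for f in graph.feature_nodes])
        m_ff = np.zeros_like(u)
        rbf_sum = np.zeros(self.N_RBF)
        if graph.edges_ff:
            ei = np.array([e[0] for e in graph.edges_ff])
            ej = np.array([e[1] for e in graph.edges_ff])
            d = np.linalg.norm(fpos[ei] - fpos[ej], axis=1)
            r = self._rbf(d, self.centers_ff)  # (E, K)
            rbf_sum = r.sum(axis=0)
            msg_to_i = np.tanh(np.concatenate([u[ej], r], axis=1) @ self.A2)
            msg_to_j = np.tanh(np.concatenate([u[ei], r], axis=1) @ self.A2)
            np.add.at(m_ff, ei, msg_to_i)
            np.add.at(m_ff, ej, msg_to_j)

        m_fp = np.zeros_like(u)
        if graph.protein_nodes and graph.edges_fp:
            onehot = np.zeros((len(graph.protein_nodes), N_CHANNELS))
            ppos = np.zeros((len(graph.protein_nodes), 3))
            for loc, ai in enumerate(graph.protein_nodes):
                ch = atom_channel(protein.atoms[ai])
                if ch is not None:
                    onehot[loc, ch] = 1.0
                ppos[loc] = protein.atoms[ai].position
            v = np.tanh(onehot @ self.A3)
            fi = np.array([e[0] for e in graph.edges_fp])
            pl = np.array([e[1] for e in graph.edges_fp])
            d = np.linalg.norm(fpos[fi] - ppos[pl], axis=1)
            r = self._rbf(d, self.centers_fp)
            msg = np.tanh(np.concatenate([v[pl], r], axis=1) @ self.A4)
            np.add.at(m_fp, fi, msg)

        z = np.tanh(np.concatenate([u, m_ff, m_fp], axis=1) @ self.A5)
        class_hist = attrs[:, :N_CLASSES].sum(axis=0) / 5.0
        counts = np.array([nf, len(graph.protein_nodes),
                           len(graph.edges_ff), len(graph.edges_fp)]) / 10.0
        return np.concatenate([z.sum(axis=0), z.mean(axis=0),
                               rbf_sum, class_hist, counts])


class QNetwork:
    """Scalar Q over protein-pharmacophore graphs: fixed invariant graph
    encoder + trainable MLP head."""

    def __init__(self, embedding_size: int = 32,
                 thresholds: GraphThresholds | None = None,
                 hidden_size: int = 64, seed: int = 0):
        thresholds = thresholds or GraphThresholds()
        self.thresholds = thresholds
        self.encoder = _GraphEncoder(embedding_size, thresholds.delta_ff,
                                     thresholds.delta_fp)
        self.head = MLP([self.encoder.dim, hidden_size, hidden_size, 1],
                        activation="relu", out="linear", seed=seed)
        self.seed = seed

    def descriptor(self, graph: PharmGraph, protein: ProteinStructure) -> np.ndarray:
        return self.encoder(graph, protein)

    def q(self, graph: PharmGraph, protein: ProteinStructure) -> float:
        return float(self.head.predict(self.descriptor(graph, protein))[0, 0])

    def q_from_descriptor(self, desc: np.ndarray) -> np.ndarray:
        return self.head.predict(np.atleast_2d(desc))[:, 0]

    def save(self, path) -> None:
        doc = {"embedding_size": self.encoder.embedding_size,
               "delta_ff": self.thresholds.delta_ff,
               "delta_fp": self.thresholds.delta_fp,
               "seed": self.seed,
               "head": self.head.state_dict()}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path) -> "QNetwork":
        doc = json.loads(Path(path).read_text())
        net = cls(doc["embedding_size"],
                  GraphThresholds(doc["delta_ff"], doc["delta_fp"]),
                  seed=doc.get("seed", 0))
        net.head = MLP.from_state_dict(doc["head"])
        return net


def q_value(network: QNetwork, graph: PharmGraph,
            protein: ProteinStructure) -> float:
    """Scalar Q-value; invariant under rigid motions and node reordering."""
    return network.q(graph, protein)


# ---------------------------------------------------------------------
# episodes and training
# ---------------------------------------------------------------------

def run_episode(env: PharmEnv, network: QNetwork | None, epsilon: float,
                rng: np.random.Generator,
                seed_feature: int | None = None,
                max_steps: int | None = None) -> list[Transition]:
    """Simulate one ε-greedy episode from a single-feature seed graph.

    With probability ε a uniformly random legal action is taken; otherwise
    the action whose resulting graph (candidates, plus the current graph
    for termination) has the highest Q.  Ends on termination, a dead end,
    or ``max_steps``.
    """
    if seed_feature is None:
        seed_feature = int(rng.integers(len(env.features)))
    state = env.reset(seed_feature)
    transitions: list[Transition] = []
    max_steps = max_steps if max_steps is not None else len(env.features) + 1
    for _ in range(max_steps):
        proposals = env.proposals(state)
        if proposals.dead_end:
            transitions.append(Transition(state, state, env.reward(state),
                                          None, True, dead_end=True))
            break
        legal = list(range(len(proposals.candidates)))
        if proposals.terminal_allowed:
            legal.append(TERMINAL)
        if epsilon > 0 and rng.random() < epsilon:
            action = legal[int(rng.integers(len(legal)))]
        else:
            if network is None:
                raise ContractError("greedy action requires a Q-network")
            best_action, best_q = None, -np.inf
            for a in legal:
                g = state if a == TERMINAL else proposals.candidates[a]
                qa = float(network.q_from_descriptor(
                    env.descriptor(network, g))[0])
                if qa > best_q:
                    best_action, best_q = a, qa
            action = best_action
        tr = env.step(state, action, proposals)
        transitions.append(tr)
        if tr.done:
            break
        state = tr.action_graph
    return transitions


@dataclass
class TrainResult:
    ensemble: list[QNetwork]
    episode_rewards: list[list[float]]  # per member, per episode (sum of r)
    episode_log: list[list[dict]]
    visited: list[set[frozenset]] = field(default_factory=list)
    # per member: feature subsets whose graphs were regression inputs


def _td_targets(entries, env: PharmEnv, target_net: QNetwork,
                gamma: float) -> np.ndarray:
    """y = r + γ·max over next proposals; the terminal option inside the
    max is valued at its exact payoff R(G); dead ends bootstrap nothing."""
    # batch-evaluate Q_target on all distinct candidate graphs
    q_cache: dict[frozenset, float] = {}
    need = []
    for tr in entries:
        if tr.next_proposals is not None:
            for g in tr.next_proposals.candidates:
                if g.key not in q_cache:
                    q_cache[g.key] = np.nan
                    need.append(g)
    if need:
        D = np.array([env.descriptor(target_net, g) for g in need])
        qs = target_net.q_from_descriptor(D)
        for g, q in zip(need, qs):
            q_cache[g.key] = float(q)
    ys = np.empty(len(entries))
    for i, tr in enumerate(entries):
        if tr.next_proposals is None:  # dead end
            ys[i] = tr.reward
            continue
        options = [q_cache[g.key] for g in tr.next_proposals.candidates]
        if tr.next_proposals.terminal_allowed:
            options.append(env.reward(tr.action_graph))
        ys[i] = tr.reward + gamma * max(options)
    return ys


def train_q(env: PharmEnv | Callable[[], PharmEnv],
            config: QTrainConfig | None = None) -> TrainResult:
    """Train an ensemble of Q-networks by replay-based TD learning.

    Each member uses a distinct seed for initialization and exploration.
    Transitions from ε-greedy episodes (exponentially decaying ε) fill a
    replay buffer; every ``fit_every`` episodes the head is fitted to TD
    targets computed with a target copy that is re-synchronized every
    ``target_sync_every`` gradient updates.  After the episode budget, a
    few fitted sweeps over the whole buffer polish the estimate.  Training
    aborts if the loss becomes non-finite.
    """
    config = config or QTrainConfig()
    env_obj = env() if callable(env) else env
    emb_size = len(env_obj.features[0].embedding) \
        if env_obj.features[0].embedding is not None else 32

    ensemble, all_rewards, all_logs, all_visited = [], [], [], []
    for member in range(config.ensemble_size):
        seed = config.seed + 7919 * member
        rng = np.random.default_rng(seed)
        net = QNetwork(emb_size, env_obj.thresholds, config.hidden_size,
                       seed=seed)
        target = copy.deepcopy(net)
        replay: list[Transition] = []
        rewards, log = [], []
        updates_since_sync = 0

        def fit_replay():
            nonlocal target, updates_since_sync
            entries = replay[-config.replay_capacity:]
            train_entries = [tr for tr in entries if not tr.done or tr.dead_end]
            if not train_entries:
                return
            ys = _td_targets(train_entries, env_obj, target, config.gamma)
            X = np.array([env_obj.descriptor(net, tr.action_graph)
                          for tr in train_entries])
            trace = net.head.fit(X, ys[:, None], loss="mse",
                                 epochs=config.fit_epochs,
                                 batch_size=config.batch_size,
                                 lr=config.learning_rate, seed=seed)
            if not np.isfinite(trace[-1]):
                raise FloatingPointError("Q-training diverged")
            n_updates = config.fit_epochs * max(
                1, int(np.ceil(len(train_entries) / config.batch_size)))
            updates_since_sync += n_updates
            if updates_since_sync >= config.target_sync_every:
                target = copy.deepcopy(net)
                updates_since_sync = 0

        sched = config.schedule
        for t in range(config.episodes):
            eps = epsilon_at(sched, t)
            transitions = run_episode(env_obj, net, eps, rng)
            replay.extend(transitions)
            if len(replay) > config.replay_capacity:
                replay = replay[-config.replay_capacity:]
            ep_reward = float(sum(tr.reward for tr in transitions))
            rewards.append(ep_reward)
            log.append({"episode": t, "epsilon": float(eps),
                        "reward": ep_reward,
                        "graph_size": transitions[-1].action_graph.n_features})
            if (t + 1) % config.fit_every == 0:
                fit_replay()

        for _ in range(config.final_fit_sweeps):
            target = copy.deepcopy(net)
            updates_since_sync = 0
            fit_replay()

        ensemble.append(net)
        all_rewards.append(rewards)
        all_logs.append(log)
        all_visited.append({tr.action_graph.key for tr in replay
                            if not tr.done or tr.dead_end})
    return TrainResult(ensemble, all_rewards, all_logs, all_visited)


# ---------------------------------------------------------------------
# exact value iteration (for enumerable tasks)
# ---------------------------------------------------------------------

def value_iteration(env: PharmEnv, gamma: float) -> dict[frozenset, float]:
    """Exact fixed point of the Bellman operator on the enumerable MDP.

    Q*(G) = R(G) + γ·max over admissible extensions' Q* and, when
    termination is allowed, the exact terminal payoff R(G).  Memoized
    recursion over feature subsets; feasible for small candidate sets.
    """
    memo: dict[frozenset, float] = {}

    def solve(selected: frozenset) -> float:
        if selected in memo:
            return memo[selected]
        graph = env.graph(tuple(selected))
        proposals = env.proposals(graph)
        r = env.reward(graph)
        options = [solve(frozenset(c.feature_indices))
                   for c in proposals.candidates]
        if proposals.terminal_allowed:
            options.append(r)
        value = r + gamma * max(options) if options else r
        memo[selected] = value
        return value

    for i in range(len(env.features)):
        solve(frozenset([i]))
    return memo


# ---------------------------------------------------------------------
# ensemble inference
# ---------------------------------------------------------------------

def build_pharmacophore(ensemble: list[QNetwork], features: list[PharmFeature],
                        protein: ProteinStructure,
                        reward_fn: Callable[[Pharmacophore], float] | None = None,
                        thresholds: GraphThresholds | None = None,
                        min_features: int = 3, top_k: int = 2,
                        ) -> list[tuple[Pharmacophore, float]]:
    """Greedy rollouts from the top-confidence seed features.

    Each ensemble member rolls out greedily (ε = 0) from each of the
    ``top_k`` highest-confidence seed features.  Terminal graphs are
    deduplicated and ranked by screening F1 when a reward oracle is
    supplied, else by terminal Q (averaged over members that produced the
    graph).  Returns at most ``ensemble_size × top_k`` pharmacophores.
    """
    thresholds = thresholds or GraphThresholds()
    conf = [(f.confidence if f.confidence is not None else 0.0, -i)
            for i, f in enumerate(features)]
    seeds = [-(c[1]) for c in sorted(conf, reverse=True)[:top_k]]

    dummy_reward = (lambda p: 0.0) if reward_fn is None else reward_fn
    env = PharmEnv(features, protein, dummy_reward, thresholds, min_features)
    rng = np.random.default_rng(0)  # unused at epsilon 0; keeps API uniform

    found: dict[frozenset, list[tuple[PharmGraph, float]]] = {}
    for net in ensemble:
        for seed_feature in seeds:
            transitions = run_episode(env, net, epsilon=0.0, rng=rng,
                                      seed_feature=seed_feature)
            terminal = transitions[-1].action_graph
            if terminal.n_features < min_features:
                continue  # dead-ended below the minimum size
            found.setdefault(terminal.key, []).append(
                (terminal, net.q(terminal, env.protein)))

    ranked = []
    for key, hits in found.items():
        graph = hits[0][0]
        if reward_fn is not None:
            score = env.reward(graph)
        else:
            score = float(np.mean([q for _, q in hits]))
        ranked.append((graph, score))
    ranked.sort(key=lambda t: -t[1])
    return [(g.pharmacophore(name=f"rank{r + 1}"), s)
            for r, (g, s) in enumerate(ranked)]
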