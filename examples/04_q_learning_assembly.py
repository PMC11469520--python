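"""Assemble a pharmacophore with the graph-building Q-learning agent.

The agent starts from a single-feature graph and repeatedly either adds a
nearby candidate feature or terminates (allowed from 3 features on).  The
reward of a graph is its screening F1.  After 300 ε-greedy training
episodes, greedy rollouts from the planted optimum's seed features should
terminate exactly at the optimal triple.
"""

import numpy as np

from qpharm.rl import (PharmEnv, QTrainConfig, library_reward, run_episode,
                       train_q)
from qpharm.synth import make_unique_optimum_task

task = make_unique_optimum_task(n_features=8, seed=1)
env = PharmEnv(task.features, task.protein, library_reward(task.library))

cfg = QTrainConfig(episodes=300, ensemble_size=1, seed=3, gamma=0.9)
result = train_q(env, cfg)
net = result.ensemble[0]

tail = np.mean(result.episode_rewards[0][-20:])
print(f"trained 1 member for {cfg.episodes} episodes; "
      f"mean reward of last 20 episodes: {tail:.2f}")
print(f"planted optimal triple: {task.optimal_indices}\n")

for seed_feature in task.optimal_indices:
    trs = run_episode(env, net, epsilon=0.0, rng=np.random.default_rng(0),
                      seed_feature=seed_feature)
    final = trs[-1].action_graph
    print(f"greedy rollout from feature {seed_feature}: "
          f"terminal subset {final.feature_indices}, "
          f"reward {trs[-1].reward:.2f}")

print("\nA terminal reward of 1.0 at the planted subset means the learned")
print("policy adds exactly the right partners and then chooses to stop.")
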