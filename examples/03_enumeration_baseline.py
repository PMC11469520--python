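"""The enumeration baseline: how good can subsets of candidate features be?

Given a set of candidate features and a labelled library, enumerate all
feature subsets of sizes 3-5 and screen each.  The maximum F1 is the best
achievable from these features (used to normalize learned pharmacophores),
and the mean is the random-selection baseline.
"""

from qpharm.screening import enumerate_baseline
from qpharm.synth import make_unique_optimum_task

task = make_unique_optimum_task(n_features=8, seed=1)
res = enumerate_baseline(task.features, task.library)

print(f"candidate features: {len(task.features)}")
print(f"subsets of size 3-5 evaluated: {res.n_evaluated}")
print(f"best F1  = {res.best_f1:.3f}  (subset "
      f"{[f.cls.name for f in res.best_pharm.features]})")
print(f"mean F1  = {res.mean_f1:.3f}  (random-selection baseline)")
print(f"planted optimum was subset {task.optimal_indices}")
print()
print("One subset screens perfectly while a random subset is near useless -")
print("exactly the gap a feature-selection policy has to close.")
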