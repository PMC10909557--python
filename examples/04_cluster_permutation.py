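"""Cluster-based permutation test on simulated tendency curves.

Builds a synthetic cohort of subject-level ordered-minus-random difference
curves with a genuine effect confined to part of the prestimulus window, runs
the sign-flip cluster permutation t-test and prints the detected clusters.
"""

import numpy as np

from predtend.stats import ClusterTestConfig, cluster_permutation_test

rng = np.random.default_rng(6)
times = np.arange(-30, 31) / 100.0  # -0.3 .. 0.3 s at 100 Hz
n_subjects = 35

curves = rng.standard_normal((n_subjects, len(times))) * 0.4
effect = (times >= -0.17) & (times <= -0.07)  # pre-activation builds up late
curves[:, effect] += 0.35

res = cluster_permutation_test(
    curves,
    times=times,
    config=ClusterTestConfig(n_permutations=10_000, cluster_alpha=0.025,
                             critical_alpha=0.025, seed=7),
)

print(f"cluster-forming |t| threshold (df={n_subjects - 1}, alpha 0.025/tail)")
for c in res.clusters:
    flag = "*" if c.p < res.config.critical_alpha else " "
    print(
        f"{flag} cluster {c.t_interval[0]:+.2f}..{c.t_interval[1]:+.2f} s, "
        f"mass = {c.mass:7.2f}, p = {c.p:.4f}"
    )
if not res.clusters:
    print("no supra-threshold clusters")

# Starred clusters survive the Monte-Carlo critical alpha of 0.025; the
# injected window -0.17..-0.07 s should be recovered as one significant
# positive cluster, while spurious clusters elsewhere should not replicate
# under the 10,000 sign-flip null.
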