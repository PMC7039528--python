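"""Benchmark EB-PRS against the comparator methods on one simulated study.

All methods consume the same summary statistics and emit the same weight
table, so scoring and evaluation are method-agnostic. P+T is tuned over its
p-value grid on the test data (best-performing-parameter reporting).
"""

import ebprs
from ebprs import evaluate as ev

cfg = ebprs.SimConfig(m=10_000, causal_prop=0.1, n0_train=1000, n1_train=1000,
                      n0_test=100, n1_test=100, seed=3)
train, test, _ = ebprs.simulate_case_control(cfg)
sumstats = ebprs.compute_sumstats(train)

print(f"{'method':12s} {'r2':>8s} {'auc':>8s}")
for name in ev.ALL_METHODS:
    weights = ev.method_weights(name, sumstats, tune_genotypes=test,
                                kappa=0.01, seed=3)
    res = ev.evaluate_scores(ev.score_with_weights(weights, test).prs,
                             test.phenotypes)
    print(f"{name:12s} {res.r2:8.4f} {res.auc:8.4f}")
print("Higher is better for both columns; r2 is the squared correlation of "
      "the score with the 0/1 phenotype, AUC the case-control ranking "
      "probability.")
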