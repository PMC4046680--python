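"""Desk-scale power comparison of SCPCA vs SPCA vs SLPCA.

Simulates causal genes at two relative-risk levels and estimates each
method's power (fraction of causal gene datasets with permutation p < 0.05).
This is a fast, scaled-down version of a full power study: fewer replicates
and smaller samples, so expect Monte-Carlo noise of several percent.
"""

import numpy as np

from scpca import SnpSet, generate_scenario, make_scenario, power, run_snpset_analysis

N_REPLICATES = 10  # increase for tighter estimates

for rr in [(1.2, 1.3), (1.5, 1.6)]:
    scenario = make_scenario(
        n_genes=5, n_causal=5, snps_per_gene=(12, 12), rr=rr,
        n_cases=100, n_controls=100, n_replicates=N_REPLICATES, seed=7,
    )
    datasets = list(generate_scenario(scenario))
    line = [f"risk {rr}:"]
    for method in ("cpca", "pca", "lpca"):
        ps = []
        for rep, gid, G, y, _ in datasets:
            res = run_snpset_analysis(
                G, y, [SnpSet(gid, np.arange(G.n_snps))], method=method,
                B=49, seed=rep * 1000 + 7, early_stop_alpha=0.05,
            )
            ps.append(res[0].p_value)
        line.append(f"{method} power={power(np.array(ps), 0.05):.2f}")
    print("  ".join(line))
# Power rises sharply from the low to the high risk level for every method.
# Between-method differences at this tiny scale sit inside Monte-Carlo
# noise: the categorical model avoids dose-effect assumptions but pays a
# variance price for its extra parameters at small n.
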