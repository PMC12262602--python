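"""Temporal dH12 contrast with permutation significance, per net arm.

dH12 = H12(round 5) - H12(baseline) per window; positive values mean
reduced haplotype diversity (stronger selection) after the intervention.
Significance comes from permuting individual pre/post labels.
"""

import numpy as np

from sweepscan import (
    SimDesign,
    delta_permutation_test,
    make_windows,
    select_cohort,
    simulate_cohorts,
)

sim = simulate_cohorts(SimDesign(seed=1))

for arm in ("PBO", "nonPBO"):
    print(f"--- {arm} arm ---")
    for contig in ("2RL", "X"):
        hap = sim.haplotypes[contig]
        sub, subframe = select_cohort(hap, sim.frame, f"arm == '{arm}'")
        windows = make_windows(sub.variants, 50)
        result = delta_permutation_test(
            sub, subframe,
            "round == 'baseline'", "round == 'round5'",
            windows, n_perm=500, seed=3,
        )
        for sweep in sim.truth["sweeps"]:
            if sweep["contig"] != contig:
                continue
            inside = [
                k for k, w in enumerate(windows)
                if w.snp_start >= sweep["site_start"] and w.snp_end <= sweep["site_end"]
            ]
            k = inside[int(np.argmax(np.abs(result.delta[inside])))]
            print(
                f"{sweep['name']:7s} dH12 = {result.delta[k]:+.3f}  "
                f"p = {result.p_values[k]:.3f}"
                f"{'  *' if result.significant[k] else ''}"
            )
# The design shifts Cyp9k1 up and Dgk down under PBO nets, and RP1 up in
# the nonPBO arm: the signs of dH12 at those loci reflect that, with '*'
# marking windows significant at the p < 0.01 permutation threshold.
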