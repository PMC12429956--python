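"""Does the analysis recover a planted approval advantage?

The generator gives genetically supported drugs (those targeting a network
containing their disease's genes) an approval odds multiplied by rho. This
script measures the approved-vs-all rate fold over replicates and compares
it with the closed-form expectation.
"""

import numpy as np

from netdrugmap import Phase, SynthConfig, expected_fold, generate_universe, related_network_rate


def pooled_fold(universe):
    num = {Phase.ALL: 0, Phase.APPROVED: 0}
    den = {Phase.ALL: 0, Phase.APPROVED: 0}
    for j in universe.diseases:
        for p in num:
            rel, dna = related_network_rate(universe, j, phase=p)
            num[p] += rel
            den[p] += dna
    return (num[Phase.APPROVED] / den[Phase.APPROVED]) / (num[Phase.ALL] / den[Phase.ALL])


for rho in (1.0, 2.0, 4.0):
    cfg = SynthConfig(approval_odds_multiplier=rho, seed=42)
    rng = np.random.default_rng(100 + int(rho))
    folds = [pooled_fold(generate_universe(cfg, rng=rng)[0]) for _ in range(50)]
    measured, se = np.mean(folds), np.std(folds, ddof=1) / np.sqrt(len(folds))
    print(f"rho={rho:.0f}: measured fold {measured:.3f} +/- {se:.3f}, "
          f"expected {expected_fold(cfg, n_rep=10):.3f}")

print("\n-> the fold is sub-linear in rho because the supported category "
      "already holds a large share of all drugs (rate saturation)")
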