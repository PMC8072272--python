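"""Bootstrap null for the SC-SI rate difference.

Builds a pool of generally expressed (GR) loci, computes the SC-SI dN/dS
difference for a focal reproductive concatenation, and locates it within the
bootstrap distribution of GR-based differences (resampling loci with
replacement, refitting the branch model per replicate).
"""

import numpy as np

import repevol as rv
from repevol.stats_compare import bootstrap_sc_si_null

rng = np.random.default_rng(21)
lengths = {"A": 0.01, "B": 0.01, "C": 0.02, "D": 0.02, "internal": 0.01}


def pool(n, sc_omega):
    cfg = rv.SimulationConfig(seed=1, n_codons=200, branch_lengths=dict(lengths))
    return [rv.simulate_alignment(
        cfg, f"l{i}", rng=np.random.default_rng(int(rng.integers(2**31))),
        omega_by_class={"SC": sc_omega, "SI": 0.3, "INTERNAL": 0.3})
        for i in range(n)]


tree = rv.LabeledTree(lengths=tuple(lengths[b] for b in ("A", "B", "C", "D", "internal")))
gr = pool(120, 0.3)            # baseline: no SC-SI difference beyond noise
rp = pool(60, 0.45)            # focal class: SC omega inflated by +0.15

fit = rv.fit_branch_model(rv.concatenate(rp), tree, rv.THREE_RATIO)
obs = fit.params.omega_by_class["SC"] - fit.params.omega_by_class["SI"]
print(f"observed focal SC-SI difference: {obs:+.4f}")

boot = bootstrap_sc_si_null(gr, obs, tree, n_reps=100, sample_size=50, seed=2)
print(f"bootstrap null (100 reps x 50 GR loci): "
      f"95% CI [{boot.ci95[0]:+.4f}, {boot.ci95[1]:+.4f}]")
print(f"observed sits at the {boot.percentile_of_observed:.1f}th percentile; "
      f"outside the CI: {boot.outside_ci}")
print("Falling above the CI means the focal class's lineage difference "
      "exceeds what GR sampling noise alone produces.")
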