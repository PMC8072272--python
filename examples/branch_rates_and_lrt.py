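"""Branch-specific dN/dS on a concatenation, with a likelihood-ratio test.

Simulates 40 loci whose self-compatible (SC) branches evolve with a higher
dN/dS than the self-incompatible (SI) branches, concatenates them, fits the
one-ratio and three-ratio models, and tests whether branch classes differ.
"""

import numpy as np

import repevol as rv

rng = np.random.default_rng(3)
cfg = rv.SimulationConfig(seed=3, n_codons=300,
                          omega_by_class={"SC": 0.45, "SI": 0.25, "INTERNAL": 0.25})
loci = [rv.simulate_alignment(cfg, f"locus{i}",
                              rng=np.random.default_rng(int(rng.integers(2**31))))
        for i in range(40)]
cat = rv.concatenate(loci, new_id="RP_concat")
print(f"concatenation: {len(loci)} loci, {cat.n_codons} codons")

tree = cfg.tree()
null = rv.fit_m0(cat, tree)
alt = rv.fit_branch_model(cat, tree, rv.THREE_RATIO)
test = rv.lrt(null.lnL, alt.lnL, df=2)

w = alt.params.omega_by_class
print(f"one-ratio omega: {null.dn_ds:.3f}  (lnL {null.lnL:.2f})")
print(f"three-ratio: SC {w['SC']:.3f}, SI {w['SI']:.3f}, "
      f"internal {w['INTERNAL']:.3f}  (lnL {alt.lnL:.2f})")
print(f"LRT: 2*dlnL = {test.stat:.3f}, df = {test.df}, p = {test.p_value:.2e}")
print("A small p means branch classes genuinely differ in dN/dS — here the "
      "planted SC elevation (+0.2) should be detected.")
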