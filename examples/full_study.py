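"""Simulate a complete study bundle and run the whole pipeline on it.

Reproductive loci are planted with an elevated dN/dS (+0.1 on every branch);
the pipeline should report a higher mean dN/dS and a larger proportion of
loci with dN/dS > 1 for the RP class than for the GR baseline.
"""

import tempfile
from pathlib import Path

from repevol.config import PipelineConfig
from repevol.pipeline import run_pipeline
from repevol.synthetic_data import SimulationConfig, simulate_study

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimulationConfig(seed=1, n_codons=120,
                           n_genes_per_class={"RP": 100, "VG": 60, "GR": 250},
                           n_housekeeping=50)
    bundle = Path(tmp) / "bundle"
    simulate_study(cfg, bundle,
                   omega_by_true_class={"RP": {"SC": 0.4, "SI": 0.4,
                                               "INTERNAL": 0.4}},
                   loci_per_class={"RP": 100, "VG": 60, "GR": 200})
    pc = PipelineConfig(seed=1, bootstrap_reps=50, bootstrap_sample_size=50)
    res = run_pipeline(bundle, Path(tmp) / "out", pc)

print("per-class summary (n, mean, SE, median dN/dS; count/proportion > 1):")
print(res["summary"].to_string(index=False))
print("\nbranch-model tests on per-class concatenations:")
cols = ["class", "n_genes", "n_codons", "stat_2dlnL", "p_value",
        "omega_SI", "omega_SC", "sc_si_diff"]
print(res["branch_tests"][cols].to_string(index=False))
if res["bootstrap"] is not None:
    b = res["bootstrap"]
    print(f"\nbootstrap SC-SI null: observed {b.observed:+.4f}, "
          f"95% CI [{b.ci95[0]:+.4f}, {b.ci95[1]:+.4f}]")
print("\nWith RP omega planted 0.1 above the 0.3 baseline, the summary should "
      "show a higher RP mean dN/dS and a larger RP share of loci with "
      "dN/dS > 1 than GR; per-locus estimates at 120 codons are noisy, so "
      "the contrast needs a few hundred loci to emerge.")
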