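import numpy as np
import pandas as pd
import pytest

from repevol.synthetic_data import SimulationConfig, TISSUES
from repevol.tree import LabeledTree


@pytest.fixture
def default_tree() -> LabeledTree:
    return LabeledTree()


def make_profile(values: dict, species=("lycopersicum", "pennellii", "habrochaites"),
                 missing: dict | None = None, default: float = 0.0) -> pd.Series:
    """Gene expression profile over (species, tissue) cells.

    ``values`` maps tissue -> TPM (applied to every species) or
    (species, tissue) -> TPM; ``missing`` maps species -> tissues with no
    data (cells simply absent, as after masking).
    """
    missing = missing or {}
    cells = {}
    for sp in species:
        for t in TISSUES:
            if t in missing.get(sp, ()):
                continue
            cells[(sp, t)] = default
    for key, v in values.items():
        if isinstance(key, tuple):
            cells[key] = v
        else:
            for sp in species:
                if (sp, key) in cells:
                    cells[(sp, key)] = v
    idx = pd.MultiIndex.from_tuples(cells.keys(), names=["species", "tissue"])
    return pd.Series(list(cells.values()), index=idx, dtype=float)


def simulate_locus(seed: int, n_codons: int = 300, omegas=None, lengths=None,
                   locus_id: str = "locus"):
    from repevol.synthetic_data import simulate_alignment

    cfg = SimulationConfig(seed=seed, n_codons=n_codons)
    if lengths is not None:
        cfg.branch_lengths = dict(lengths)
    if omegas is not None:
        cfg.omega_by_class = dict(omegas)
    return simulate_alignment(cfg, locus_id, rng=np.random.default_rng(seed))
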