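"""Ground-truthed synthetic inputs for the whole pipeline.

Two generators: codon alignments evolved forward along the labeled 4-taxon
tree under branch-class-specific GY94 parameters (short SC tip branches,
longer SI tips, one internal branch — echoing the strong branch-length
asymmetry between selfing and outcrossing lineages), and replicate-level
RNA-seq count tables whose underlying TPM structure plants known gene
classes (reproductive / vegetative / general / tissue-specific) around the
>2 and <0.5 TPM classification thresholds.

Everything is driven by a single seed: identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import CodonAlignment, write_alignment_fasta
from .codon_models import CodonModelParams, _Spectral, build_rate_matrix
from .genetics import N_CODONS, uniform_frequencies
from .tree import BRANCH_NAMES, DEFAULT_TAXA, INTERNAL, SC, SI, LabeledTree

#: The 8 classification tissues.
TISSUES = ("leaf", "root", "stem", "seed", "meristem", "style", "pollen", "ovule")
REPRODUCTIVE_TISSUES = ("style", "pollen", "ovule")
VEGETATIVE_TISSUES = ("leaf", "root", "stem", "seed", "meristem")

#: Tissues with no data for the incompletely sampled species.
DEFAULT_MISSING = {"pimpinellifolium": ("style", "pollen")}


@dataclass
class SimulationConfig:
    """Study-scale knobs for the synthetic generators.

    Branch lengths default to the SC-short / SI-long asymmetry (expected
    substitutions per codon); omegas are per branch class. Expression
    defaults plant classes well clear of the 2 / 0.5 TPM thresholds with
    negative-binomial replicate noise (dispersion = NB size parameter).
    """

    seed: int = 0
    taxa: tuple[str, ...] = DEFAULT_TAXA
    # sequence side
    n_codons: int = 300
    branch_lengths: dict[str, float] = field(
        default_factory=lambda: {"A": 0.002, "B": 0.002, "C": 0.02, "D": 0.02,
                                 "internal": 0.01})
    omega_by_class: dict[str, float] = field(
        default_factory=lambda: {SC: 0.3, SI: 0.3, INTERNAL: 0.3})
    kappa: float = 2.0
    codon_freqs: np.ndarray = field(default_factory=uniform_frequencies)
    # expression side
    n_genes_per_class: dict[str, int] = field(
        default_factory=lambda: {"RP": 60, "VG": 80, "GR": 400})
    n_housekeeping: int = 100
    n_replicates: int = 3
    expressed_tpm: float = 50.0
    background_tpm: float = 0.05
    dispersion: float = 10.0
    library_size: int = 2_000_000
    gene_length_range: tuple[int, int] = (600, 3000)
    missing_tissues: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MISSING))

    def tree(self) -> LabeledTree:
        return LabeledTree(taxa=tuple(self.taxa),
                           lengths=tuple(self.branch_lengths[b] for b in BRANCH_NAMES))


def _sample_children(P: np.ndarray, parents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw child states for each site given parent states and P(t)."""
    out = np.empty_like(parents)
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parents.shape[0])
    for state in np.unique(parents):
        mask = parents == state
        out[mask] = np.searchsorted(cum[state], u[mask], side="right")
    return np.minimum(out, N_CODONS - 1)


def simulate_alignment(config: SimulationConfig, locus_id: str = "locus",
                       rng: np.random.Generator | None = None,
                       omega_by_class: dict[str, float] | None = None,
                       n_codons: int | None = None) -> CodonAlignment:
    """Evolve one locus forward along the labeled tree.

    Root codons are drawn from the stationary frequencies at the internal
    node adjacent to the SC cherry; each branch then transforms states via
    its class-specific transition matrix.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    omegas = omega_by_class or config.omega_by_class
    n = n_codons or config.n_codons
    params = CodonModelParams(config.kappa, dict(omegas), config.codon_freqs)
    tree = config.tree()
    classes = tree.branch_classes
    lengths = tree.branch_lengths
    P = {}
    spectral_cache: dict[str, _Spectral] = {}
    for name in BRANCH_NAMES:
        cls = classes[name]
        if cls not in spectral_cache:
            spectral_cache[cls] = _Spectral(build_rate_matrix(params, cls),
                                            config.codon_freqs)
        P[name] = spectral_cache[cls].P(lengths[name])
        P[name] = P[name] / P[name].sum(axis=1, keepdims=True)
    root = rng.choice(N_CODONS, size=n, p=config.codon_freqs / config.codon_freqs.sum())
    node_u = root  # internal node adjacent to the SC cherry
    node_v = _sample_children(P["internal"], node_u, rng)
    rows = np.stack([
        _sample_children(P["A"], node_u, rng),
        _sample_children(P["B"], node_u, rng),
        _sample_children(P["C"], node_v, rng),
        _sample_children(P["D"], node_v, rng),
    ])
    return CodonAlignment(locus_id, tuple(config.taxa), rows.astype(np.int16))


def _planted_profiles(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene planted TPM by tissue, plus true class labels.

    RP genes express in one reproductive tissue, VG in one vegetative
    tissue, GR in one of each; all other tissues sit at the background
    level, far below the 0.5 TPM trace threshold.
    """
    records = []
    gi = 0
    hi, lo = config.expressed_tpm, config.background_tpm
    for cls, n in config.n_genes_per_class.items():
        for k in range(n):
            tpm = dict.fromkeys(TISSUES, lo)
            if cls == "RP":
                focal = REPRODUCTIVE_TISSUES[k % 3]
                tpm[focal] = hi
            elif cls == "VG":
                focal = VEGETATIVE_TISSUES[k % 5]
                tpm[focal] = hi
            elif cls == "GR":
                rep = REPRODUCTIVE_TISSUES[k % 3]
                veg = VEGETATIVE_TISSUES[k % 5]
                tpm[rep] = hi
                tpm[veg] = hi
                focal = ""
            else:
                raise ValueError(f"unknown planted class {cls!r}")
            records.append({"gene_id": f"g{gi:05d}", "true_class": cls,
                            "true_tissue": focal if cls in ("RP", "VG") else "",
                            **tpm})
            gi += 1
    df = pd.DataFrame(records)
    # Broadly expressed housekeeping pool absorbing the rest of each
    # library's 1e6 TPM budget, so planted values survive normalization.
    # These genes are expressed in every tissue, hence genuinely GR.
    if config.n_housekeeping:
        hk = []
        col_sums = {t: df[t].sum() for t in TISSUES}
        for k in range(config.n_housekeeping):
            tpm = {t: max((1e6 - col_sums[t]) / config.n_housekeeping, 1.0)
                   for t in TISSUES}
            hk.append({"gene_id": f"hk{k:04d}", "true_class": "GR",
                       "true_tissue": "", **tpm})
        df = pd.concat([df, pd.DataFrame(hk)], ignore_index=True)
    df["length"] = rng.integers(*config.gene_length_range, size=len(df))
    return df


def simulate_counts(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate replicate-level count tables with planted classes.

    Returns (counts, libraries, truth). Counts: gene_id, length and one
    column per library. Expected counts are proportional to planted TPM x
    gene length within each library; replicate noise is negative binomial
    with the configured dispersion. Style/pollen libraries are omitted for
    species listed in ``missing_tissues``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = _planted_profiles(config, rng)
    lengths = truth["length"].to_numpy()
    libs = []
    counts = {"gene_id": truth["gene_id"], "length": lengths}
    for species in config.taxa:
        missing = set(config.missing_tissues.get(species, ()))
        for tissue in TISSUES:
            if tissue in missing:
                continue
            tpm = truth[tissue].to_numpy(dtype=float)
            rel = tpm * lengths
            expected = config.library_size * rel / rel.sum()
            for rep in range(1, config.n_replicates + 1):
                lib_id = f"{species}_{tissue}_r{rep}"
                size = config.dispersion
                p = size / (size + expected)
                counts[lib_id] = rng.negative_binomial(size, p)
                libs.append({"library_id": lib_id, "species": species,
                             "tissue": tissue, "replicate": rep})
    counts_df = pd.DataFrame(counts)
    libraries = pd.DataFrame(libs)
    truth_cols = ["gene_id", "true_class", "true_tissue", "length", *TISSUES]
    return counts_df, libraries, truth[truth_cols]


def simulate_study(config: SimulationConfig, out_dir,
                   omega_by_true_class: dict[str, dict[str, float]] | None = None,
                   loci_per_class: dict[str, int] | None = None) -> Path:
    """Write a complete input bundle: locus FASTAs, counts, metadata, truth.

    One alignment is simulated per classified gene (capped per class by
    ``loci_per_class``), optionally with class-specific omega maps (e.g. an
    inflated SC omega for RP loci) so downstream contrasts have a known
    direction. The directory layout matches what the pipeline consumes.
    """
    out = Path(out_dir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    counts_df, libraries, truth = simulate_counts(config, rng)
    counts_df.to_csv(out / "counts.tsv", sep="\t", index=False)
    libraries.to_csv(out / "libraries.tsv", sep="\t", index=False)

    omega_by_true_class = omega_by_true_class or {}
    caps = loci_per_class or {}
    manifest, truth_rows = [], []
    per_class_seen: dict[str, int] = {}
    for row in truth.itertuples():
        cls = row.true_class
        seen = per_class_seen.get(cls, 0)
        cap = caps.get(cls)
        if cap is not None and seen >= cap:
            continue
        per_class_seen[cls] = seen + 1
        omegas = omega_by_true_class.get(cls, config.omega_by_class)
        aln = simulate_alignment(config, locus_id=row.gene_id, rng=rng,
                                 omega_by_class=omegas)
        rel = f"alignments/{row.gene_id}.fasta"
        write_alignment_fasta(aln, out / rel)
        manifest.append({"locus_id": row.gene_id, "path": rel})
        truth_rows.append({"gene_id": row.gene_id,
                           **{f"omega_{k}": v for k, v in omegas.items()}})
    pd.DataFrame(manifest).to_csv(out / "loci.tsv", sep="\t", index=False)
    truth.merge(pd.DataFrame(truth_rows), on="gene_id", how="left") \
         .to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"seed": config.seed, "n_codons": config.n_codons,
                        "taxa": list(config.taxa),
                        "branch_lengths": dict(config.branch_lengths),
                        "omega_by_class": {k: float(v) for k, v in config.omega_by_class.items()},
                        "kappa": config.kappa}, fh)
    return out
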