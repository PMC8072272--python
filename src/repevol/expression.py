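"""TPM normalization and rule-based gene classification from expression.

The classification scheme works on per-(species, tissue) mean TPM values over
eight tissues (leaf, root, stem, seed, vegetative meristem, style, pollen,
ovule). A gene is called "expressed" in a tissue at TPM > 2 and shows "trace"
expression below TPM < 0.5; classes are assigned by majority vote over the
three fully sampled species (both conditions of a vote are evaluated within
the same species). Broad classes: reproductive-exclusive (RP),
vegetative-exclusive (VG), general (GR, expressed on both sides), otherwise
unclassified. The same voting yields single-tissue-specific labels and the
gametophytic (haploid: pollen, ovule) vs sporophytic (diploid, including
style) partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import REPRODUCTIVE_TISSUES, TISSUES, VEGETATIVE_TISSUES

EXPRESSED_TPM = 2.0
TRACE_TPM = 0.5

GAMETOPHYTIC_TISSUES = ("pollen", "ovule")
SPOROPHYTIC_TISSUES = ("leaf", "root", "stem", "seed", "meristem", "style")

#: Species used for classification votes (those with all tissues sampled).
DEFAULT_VOTING_SPECIES = ("lycopersicum", "pennellii", "habrochaites")


@dataclass
class ClassificationRules:
    expressed_tpm: float = EXPRESSED_TPM
    trace_tpm: float = TRACE_TPM
    voting_species: tuple[str, ...] = DEFAULT_VOTING_SPECIES
    min_votes: int = 2
    reproductive: tuple[str, ...] = REPRODUCTIVE_TISSUES
    vegetative: tuple[str, ...] = VEGETATIVE_TISSUES
    gametophytic: tuple[str, ...] = GAMETOPHYTIC_TISSUES
    sporophytic: tuple[str, ...] = SPOROPHYTIC_TISSUES


def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-library TPM from a counts table.

    ``counts`` must have columns ``gene_id``, ``length`` (bp) and one column
    per library. TPM_g = 1e6 * (c_g / L_g) / sum_j (c_j / L_j); every library
    column sums to 1e6.
    """
    lengths = counts["length"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    lib_cols = [c for c in counts.columns if c not in ("gene_id", "length")]
    out = {"gene_id": counts["gene_id"]}
    for col in lib_cols:
        rate = counts[col].to_numpy(dtype=float) / lengths
        total = rate.sum()
        if total <= 0:
            raise ValueError(f"library {col!r} has no mapped reads")
        out[col] = 1e6 * rate / total
    return pd.DataFrame(out)


def tissue_means(tpm: pd.DataFrame, libraries: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM per (species, tissue), averaged over available replicates.

    Returns a gene x (species, tissue) frame with a two-level column index;
    (species, tissue) combinations with no libraries are simply absent —
    they are recorded as missing, never imputed.
    """
    meta = libraries.set_index("library_id")
    cols = {}
    for (species, tissue), group in meta.groupby(["species", "tissue"], sort=True):
        libs = [l for l in group.index if l in tpm.columns]
        if not libs:
            continue
        cols[(species, tissue)] = tpm[libs].mean(axis=1)
    out = pd.DataFrame(cols)
    out.index = tpm["gene_id"]
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["species", "tissue"])
    return out


def _species_tpm(profile: pd.Series, species: str, tissues) -> np.ndarray:
    """TPM values for the tissues a species actually has data for."""
    vals = []
    for t in tissues:
        if (species, t) in profile.index:
            vals.append(profile[(species, t)])
    return np.asarray(vals, dtype=float)


def _partition_vote(profile: pd.Series, species: str, on, off,
                    rules: ClassificationRules) -> str | None:
    """One species' vote for a two-sided partition.

    "on-exclusive" iff expressed (> expressed_tpm) in >=1 'on' tissue and at
    trace (< trace_tpm) in every 'off' tissue; mirror-image for
    "off-exclusive"; "both" iff expressed on both sides. Votes are mutually
    exclusive within a species.
    """
    on_vals = _species_tpm(profile, species, on)
    off_vals = _species_tpm(profile, species, off)
    on_hi = on_vals.size and on_vals.max() > rules.expressed_tpm
    off_hi = off_vals.size and off_vals.max() > rules.expressed_tpm
    on_quiet = (not off_vals.size) or off_vals.max() < rules.trace_tpm
    off_quiet = (not on_vals.size) or on_vals.max() < rules.trace_tpm
    if on_hi and on_quiet:
        return "ON"
    if off_hi and off_quiet:
        return "OFF"
    if on_hi and off_hi:
        return "BOTH"
    return None


def _majority(votes, rules: ClassificationRules) -> str | None:
    counts: dict[str, int] = {}
    for v in votes:
        if v is not None:
            counts[v] = counts.get(v, 0) + 1
    for label, n in counts.items():
        if n >= rules.min_votes:
            return label
    return None


def classify_broad(profile: pd.Series, rules: ClassificationRules | None = None) -> str:
    """Broad class: RP / VG / GR / UNCLASSIFIED by 2-of-3 species vote."""
    rules = rules or ClassificationRules()
    votes = [_partition_vote(profile, sp, rules.reproductive, rules.vegetative, rules)
             for sp in rules.voting_species]
    label = _majority(votes, rules)
    return {"ON": "RP", "OFF": "VG", "BOTH": "GR", None: "UNCLASSIFIED"}[label]


def classify_tissue_specific(profile: pd.Series,
                             rules: ClassificationRules | None = None) -> str | None:
    """Single-tissue-specific label, or None.

    A species votes for a focal tissue iff that tissue is expressed
    (> expressed_tpm) and every other classification tissue is at trace
    (< trace_tpm); a tissue wins with >= 2 of 3 votes. At most one tissue can
    win (votes within a species are mutually exclusive across tissues).
    """
    rules = rules or ClassificationRules()
    for focal in TISSUES:
        others = tuple(t for t in TISSUES if t != focal)
        votes = []
        for sp in rules.voting_species:
            focal_vals = _species_tpm(profile, sp, (focal,))
            other_vals = _species_tpm(profile, sp, others)
            hit = (focal_vals.size and focal_vals.max() > rules.expressed_tpm
                   and ((not other_vals.size) or other_vals.max() < rules.trace_tpm))
            votes.append("ON" if hit else None)
        if _majority(votes, rules) == "ON":
            return focal
    return None


def classify_ploidy(profile: pd.Series,
                    rules: ClassificationRules | None = None) -> dict[str, str]:
    """Gametophytic vs sporophytic expression classes.

    Returns {"ploidy", "ovule_class", "pollen_class"}; ploidy is one of
    GAMETOPHYTIC_ONLY / SPOROPHYTIC_ONLY / GAM_PLUS_SPORO / UNCLASSIFIED.
    The ovule/pollen sub-classes distinguish tissue-only loci from those also
    expressed in at least one sporophytic (diploid) tissue.
    """
    rules = rules or ClassificationRules()
    votes = [_partition_vote(profile, sp, rules.gametophytic, rules.sporophytic, rules)
             for sp in rules.voting_species]
    ploidy = {"ON": "GAMETOPHYTIC_ONLY", "OFF": "SPOROPHYTIC_ONLY",
              "BOTH": "GAM_PLUS_SPORO", None: "UNCLASSIFIED"}[_majority(votes, rules)]

    def tissue_class(tissue: str) -> str:
        votes = [_partition_vote(profile, sp, (tissue,), rules.sporophytic, rules)
                 for sp in rules.voting_species]
        label = _majority(votes, rules)
        if label == "ON":
            return "TISSUE_ONLY"
        if label == "BOTH":
            return "TISSUE_PLUS_SPORO"
        return "NA"

    return {"ploidy": ploidy, "ovule_class": tissue_class("ovule"),
            "pollen_class": tissue_class("pollen")}


def expression_breadth(profile: pd.Series,
                       rules: ClassificationRules | None = None) -> int:
    """Number of the 8 tissues expressed (> threshold) in *every* species
    with data for that tissue (0-8)."""
    rules = rules or ClassificationRules()
    breadth = 0
    for tissue in TISSUES:
        vals = [profile[(sp, tissue)] for sp in rules.voting_species
                if (sp, tissue) in profile.index]
        if vals and all(v > rules.expressed_tpm for v in vals):
            breadth += 1
    return breadth


def mean_expression(profile: pd.Series,
                    rules: ClassificationRules | None = None) -> float:
    """Mean TPM over the (species, tissue) cells where the locus is expressed
    (> threshold); 0 if expressed nowhere."""
    rules = rules or ClassificationRules()
    vals = profile.to_numpy(dtype=float)
    expressed = vals[vals > rules.expressed_tpm]
    return float(expressed.mean()) if expressed.size else 0.0


def classify_genes(mean_tpm: pd.DataFrame,
                   rules: ClassificationRules | None = None) -> pd.DataFrame:
    """Apply every classifier to each gene of a tissue-mean TPM table.

    Returns one row per gene: broad, tissue_specific, ploidy, ovule_class,
    pollen_class, breadth, mean_expr. Deterministic and independent of
    replicate or row order.
    """
    rules = rules or ClassificationRules()
    rows = []
    for gene_id, profile in mean_tpm.iterrows():
        broad = classify_broad(profile, rules)
        tissue = classify_tissue_specific(profile, rules)
        ploidy = classify_ploidy(profile, rules)
        rows.append({
            "gene_id": gene_id,
            "broad": broad,
            "tissue_specific": tissue or "",
            **ploidy,
            "breadth": expression_breadth(profile, rules),
            "mean_expr": mean_expression(profile, rules),
        })
    return pd.DataFrame(rows)
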