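"""End-to-end pipeline over an input bundle.

Stages: expression classification -> per-locus M0 dN/dS -> estimate filter
-> class summaries and comparisons -> branch-model fits on per-class
concatenations with LRTs -> bootstrap SC-SI null. Every stage writes a TSV
artifact and the run ends with a manifest recording versions, seed, config
hash and per-stage locus counts (no silent drops).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import AlignmentError, concatenate, read_alignment_fasta
from .codon_models import M0, fit_branch_model, fit_m0, lrt
from .config import PipelineConfig
from .expression import ClassificationRules, classify_genes, tissue_means, tpm_normalize
from .stats_compare import (
    bootstrap_sc_si_null,
    chi_square_independence,
    filter_records,
    fisher_one_sided,
    gamma_glm_identity,
    letter_display,
    pairwise_contrasts,
    summarize_class,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def classify_stage(bundle: Path, config: PipelineConfig) -> pd.DataFrame:
    counts = pd.read_csv(bundle / "counts.tsv", sep="\t")
    libraries = pd.read_csv(bundle / "libraries.tsv", sep="\t")
    tpm = tpm_normalize(counts)
    means = tissue_means(tpm, libraries)
    rules = ClassificationRules(expressed_tpm=config.expressed_tpm,
                                trace_tpm=config.trace_tpm,
                                voting_species=config.voting_species)
    return classify_genes(means, rules)


def dnds_stage(bundle: Path, config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    manifest = pd.read_csv(bundle / "loci.tsv", sep="\t")
    tree = config.tree()
    rows, alignments = [], {}
    n_rejected = 0
    for rec in manifest.itertuples():
        try:
            aln = read_alignment_fasta(bundle / rec.path, expected_taxa=config.taxa,
                                       min_codons=config.min_codons,
                                       aliases=config.taxon_aliases)
        except AlignmentError as exc:
            logger.info("locus %s rejected: %s", rec.locus_id, exc)
            n_rejected += 1
            continue
        aln.locus_id = rec.locus_id
        fit = fit_m0(aln, tree, freq_scheme=config.freq_scheme)
        alignments[rec.locus_id] = aln
        rows.append({"gene_id": rec.locus_id, "model": M0, "omega": fit.dn_ds,
                     "kappa": fit.params.kappa, "dN": fit.dN, "dS": fit.dS,
                     "lnL": fit.lnL, "n_codons": aln.n_codons,
                     "converged": fit.converged,
                     "degenerate": "degenerate" in fit.notes,
                     "flags": ";".join(fit.notes)})
    df = pd.DataFrame(rows)
    return df, {"alignments": alignments, "n_rejected": n_rejected}


def compare_stage(records: pd.DataFrame, config: PipelineConfig) -> dict:
    """Class summaries, gamma GLM contrasts and proportion tests on RP/VG/GR."""
    classed = records[records["broad"].isin(["RP", "VG", "GR"])]
    summary = summarize_class(classed, "broad")
    out = {"summary": summary}
    if classed["broad"].nunique() >= 2 and len(classed) >= 10:
        glm = gamma_glm_identity(classed["omega"], classed["broad"])
        contrasts = pairwise_contrasts(glm, seed=config.stage_seed("contrasts"))
        letters = letter_display(sorted(classed["broad"].unique()), contrasts)
        out["contrasts"] = contrasts
        out["letters"] = letters
        by = {row["broad"]: row for _, row in summary.iterrows()}
        if {"RP", "GR"} <= by.keys():
            out["fisher_rp_vs_gr"] = fisher_one_sided(
                int(by["RP"]["n_gt1"]), int(by["RP"]["n"]),
                int(by["GR"]["n_gt1"]), int(by["GR"]["n"]))
            table = [[by[c]["n_gt1"] for c in by],
                     [by[c]["n"] - by[c]["n_gt1"] for c in by]]
            if sum(table[0]) > 0:  # chi-square undefined with an all-zero row
                out["chi2_proportions"] = chi_square_independence(table)
    return out


def branch_stage(records: pd.DataFrame, alignments: dict, config: PipelineConfig) -> pd.DataFrame:
    """Branch-model fits + LRT on per-class concatenations (Table-4 layout)."""
    tree = config.tree()
    rows = []
    for cls in ("GR", "RP", "VG"):
        ids = records.loc[records["broad"] == cls, "gene_id"]
        alns = [alignments[g] for g in ids if g in alignments]
        if len(alns) < 2:
            continue
        cat = concatenate(alns, new_id=cls)
        null = fit_m0(cat, tree, freq_scheme=config.freq_scheme)
        alt = fit_branch_model(cat, tree, config.branch_scheme,
                               freq_scheme=config.freq_scheme)
        df = 2 if config.branch_scheme == "THREE_RATIO" else 1
        test = lrt(null.lnL, alt.lnL, df)
        w = alt.params.omega_by_class
        rows.append({"class": cls, "n_genes": len(alns), "n_codons": cat.n_codons,
                     "lnL_null": null.lnL, "lnL_alt": alt.lnL,
                     "stat_2dlnL": test.stat, "p_value": test.p_value,
                     "omega_SI": w.get("SI"), "omega_SC": w.get("SC"),
                     "omega_internal": w.get("INTERNAL"),
                     "sc_si_diff": w.get("SC") - w.get("SI")})
    return pd.DataFrame(rows)


def run_pipeline(bundle_dir, out_dir, config: PipelineConfig | None = None) -> dict:
    """Run every stage on a bundle directory and write a report bundle.

    Returns a dict of in-memory results; artifacts (classification.tsv,
    dnds.tsv, summary.tsv, branch_tests.tsv, bootstrap.json, manifest.json)
    are written under ``out_dir``.
    """
    config = config or PipelineConfig()
    bundle, out = Path(bundle_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    counts_log: dict = {}

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    classification = stage("classify", classify_stage, bundle, config)
    classification.to_csv(out / "classification.tsv", sep="\t", index=False)
    counts_log["classified_genes"] = len(classification)

    dnds, extra = stage("dnds", dnds_stage, bundle, config)
    dnds.to_csv(out / "dnds.tsv", sep="\t", index=False)
    counts_log["loci_fit"] = len(dnds)
    counts_log["loci_rejected_by_length"] = extra["n_rejected"]

    records = dnds.merge(classification, on="gene_id", how="inner")
    filtered = stage("filter", filter_records, records)
    counts_log["loci_after_filter"] = len(filtered)
    counts_log["filter_drops"] = filtered.attrs.get("drops", {})

    comparison = stage("compare", compare_stage, filtered, config)
    comparison["summary"].to_csv(out / "summary.tsv", sep="\t", index=False)
    results["summary"] = comparison["summary"]
    results["comparison"] = comparison

    branch = stage("branch-test", branch_stage, filtered, extra["alignments"], config)
    branch.to_csv(out / "branch_tests.tsv", sep="\t", index=False)
    results["branch_tests"] = branch

    boot = None
    gr_ids = filtered.loc[filtered["broad"] == "GR", "gene_id"]
    gr_alns = [extra["alignments"][g] for g in gr_ids if g in extra["alignments"]]
    if (config.bootstrap_reps > 0 and not branch.empty
            and {"GR", "RP"} <= set(branch["class"]) and len(gr_alns) >= 5):
        observed = float(branch.loc[branch["class"] == "RP", "sc_si_diff"].iloc[0])
        sample = min(config.bootstrap_sample_size, len(gr_alns))
        boot = stage("bootstrap-null", bootstrap_sc_si_null, gr_alns, observed,
                     config.tree(), config.bootstrap_reps, sample,
                     config.stage_seed("bootstrap"), config.bootstrap_replace,
                     config.branch_scheme)
        pd.DataFrame({"replicate": np.arange(boot.n_reps), "diff": boot.diffs}) \
            .to_csv(out / "bootstrap_diffs.tsv", sep="\t", index=False)
        with open(out / "bootstrap.json", "w") as fh:
            json.dump({"n_reps": boot.n_reps, "sample_size": boot.sample_size,
                       "ci95": list(boot.ci95), "observed": boot.observed,
                       "percentile_of_observed": boot.percentile_of_observed,
                       "outside_ci": boot.outside_ci}, fh, indent=2)
    results["bootstrap"] = boot

    manifest = {"repevol_version": __version__, "seed": config.seed,
                "config_hash": _config_hash(config), "counts": counts_log}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    results["records"] = filtered
    return results
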