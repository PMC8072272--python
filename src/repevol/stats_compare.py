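"""Comparative statistics on per-locus dN/dS by gene class.

Covers the filtering of unreliable estimates (dN/dS > 10, non-converged or
degenerate fits), gamma GLMs with identity link and single-step-adjusted
pairwise contrasts (max-|z| multiplicity adjustment over the jointly normal
contrast vector), chi-square and one-sided Fisher's exact tests on the
proportion of loci with dN/dS > 1, a bootstrap null distribution for the
SC-SI lineage rate difference built from generally expressed loci, and the
sqrt(dN/dS) ~ expression x class regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .alignment import CodonAlignment, concatenate
from .codon_models import THREE_RATIO, fit_branch_model
from .tree import LabeledTree

OMEGA_CEILING = 10.0


@dataclass
class ContrastResult:
    group_a: str
    group_b: str
    estimate: float
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class BootstrapNull:
    n_reps: int
    sample_size: int
    diffs: np.ndarray
    ci95: tuple[float, float]
    observed: float
    percentile_of_observed: float

    @property
    def outside_ci(self) -> bool:
        return not (self.ci95[0] <= self.observed <= self.ci95[1])


def filter_records(records: pd.DataFrame, omega_col: str = "omega",
                   ceiling: float = OMEGA_CEILING) -> pd.DataFrame:
    """Drop loci with dN/dS above the ceiling (strict >), non-converged or
    degenerate fits. Drop counts by reason are attached as ``.attrs['drops']``."""
    df = records.copy()
    drops = {}
    if "converged" in df.columns:
        bad = ~df["converged"].astype(bool)
        drops["not_converged"] = int(bad.sum())
        df = df[~bad]
    if "degenerate" in df.columns:
        bad = df["degenerate"].astype(bool)
        drops["degenerate"] = int(bad.sum())
        df = df[~bad]
    omega = df[omega_col].astype(float)
    bad = omega.isna() | (omega > ceiling)
    drops["omega_ceiling"] = int(bad.sum())
    df = df[~bad].copy()
    df.attrs["drops"] = drops
    return df


def _prepare_gamma(y: np.ndarray) -> tuple[np.ndarray, float | None]:
    """Replace zeros by half the smallest positive value (gamma support)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("dN/dS values must be non-negative")
    positives = y[y > 0]
    if positives.size == 0:
        raise ValueError("all values are zero; gamma GLM undefined")
    replacement = positives.min() / 2.0
    n_zero = int((y == 0).sum())
    y = np.where(y == 0, replacement, y)
    return y, (replacement if n_zero else None)


def gamma_glm_identity(values, groups):
    """Gamma GLM with identity link: one mean per group.

    ``values`` are per-locus dN/dS (zeros replaced by half the smallest
    positive value, logged on the result as ``zero_replacement``); ``groups``
    a parallel factor. Returns the fitted statsmodels results object with
    coefficients in group-sorted order (dummy coding dropped: first group is
    the intercept).
    """
    y, replacement = _prepare_gamma(np.asarray(values, dtype=float))
    groups = pd.Categorical(groups)
    X = pd.get_dummies(pd.Series(groups), drop_first=False, dtype=float)
    with warnings.catch_warnings():
        # identity link on the gamma family is a deliberate modeling choice
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X[sorted(X.columns)], family=sm.families.Gamma(
            link=sm.families.links.Identity()))
        res = model.fit(maxiter=200)
    if not res.converged:
        raise RuntimeError("gamma GLM failed to converge")
    res.zero_replacement = replacement
    return res


def max_modulus_adjust(z, corr, n_draws: int = 200_000, seed: int = 0) -> np.ndarray:
    """Single-step adjusted p-values: P(max_j |Z_j| >= |z_k|), Z ~ N(0, corr).

    Estimated by Monte Carlo with a fixed seed; the eigen square root makes
    near-singular contrast correlation matrices safe.
    """
    z = np.asarray(z, dtype=float)
    corr = 0.5 * (np.asarray(corr, dtype=float) + np.asarray(corr, dtype=float).T)
    w, U = np.linalg.eigh(corr)
    factor = U * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, len(z))) @ factor.T
    maxmod = np.abs(draws).max(axis=1)
    return np.array([np.mean(maxmod >= abs(zk)) for zk in z])


def pairwise_contrasts(fit, n_draws: int = 200_000, seed: int = 0,
                       alpha: float = 0.05) -> list[ContrastResult]:
    """All pairwise group contrasts with single-step adjustment.

    For contrast matrix C the z statistics are z = C b / sqrt(diag(C V C')).
    The adjusted p-value of contrast k is P(max_j |Z_j| >= |z_k|) where Z is
    multivariate normal with the correlation matrix of the contrasts,
    estimated by Monte Carlo with a fixed seed.
    """
    names = list(fit.params.index)
    k = len(names)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    C = np.zeros((len(pairs), k))
    for r, (i, j) in enumerate(pairs):
        C[r, j] = 1.0
        C[r, i] = -1.0
    b = fit.params.to_numpy()
    V = fit.cov_params().to_numpy()
    est = C @ b
    var = np.einsum("ij,jk,ik->i", C, V, C)
    z = est / np.sqrt(var)
    p_raw = 2 * sps.norm.sf(np.abs(z))
    corr = (C @ V @ C.T) / np.sqrt(np.outer(var, var))
    p_adj = np.maximum(max_modulus_adjust(z, corr, n_draws, seed), p_raw)
    return [
        ContrastResult(names[i], names[j], float(est[r]), float(z[r]),
                       float(p_raw[r]), float(min(p_adj[r], 1.0)))
        for r, (i, j) in enumerate(pairs)
    ]


def letter_display(groups, contrasts: list[ContrastResult],
                   alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from adjusted pairwise p-values.

    Insert-and-absorb: groups sharing a letter are not significantly
    different at ``alpha`` after adjustment.
    """
    groups = list(groups)
    sig = {frozenset((c.group_a, c.group_b)) for c in contrasts
           if c.p_adjusted < alpha}
    letters: list[set[str]] = [set(groups)]
    for pair in sig:
        a, b = tuple(pair)
        for s in list(letters):
            if a in s and b in s:
                letters.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in letters):
                        letters.append(cand)
    letters.sort(key=lambda s: min(groups.index(g) for g in s))
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        for g in groups:
            if g in s:
                out[g] += chr(ord("a") + i)
    return out


def fisher_one_sided(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided Fisher's exact test for enrichment in group 1.

    Upper-tail hypergeometric probability of >= k1 successes in group 1
    given the table margins.
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(sps.fisher_exact(table, alternative="greater").pvalue)


def chi_square_independence(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2 x k count table.

    Returns (statistic, df, p). No continuity correction by default.
    """
    table = np.asarray(table, dtype=float)
    stat, p, df, _ = sps.chi2_contingency(table, correction=correction)
    return float(stat), int(df), float(p)


def summarize_class(records: pd.DataFrame, group_col: str,
                    omega_col: str = "omega") -> pd.DataFrame:
    """Per-group n, mean, SE, median dN/dS plus count and proportion > 1."""
    rows = []
    for group, sub in records.groupby(group_col, sort=False):
        omega = sub[omega_col].astype(float).to_numpy()
        n = len(omega)
        n_pos = int((omega > 1).sum())
        rows.append({
            group_col: group, "n": n,
            "mean": float(omega.mean()) if n else float("nan"),
            "se": float(omega.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
            "median": float(np.median(omega)) if n else float("nan"),
            "n_gt1": n_pos,
            "prop_gt1": n_pos / n if n else float("nan"),
        })
    return pd.DataFrame(rows)


def bootstrap_sc_si_null(gr_alignments: list[CodonAlignment],
                         observed_diff: float,
                         tree: LabeledTree | None = None,
                         n_reps: int = 1000, sample_size: int = 500,
                         seed: int = 0, replace: bool = True,
                         scheme: str = THREE_RATIO,
                         fast: bool = True) -> BootstrapNull:
    """Bootstrap null for the SC-SI dN/dS difference from GR loci.

    Each replicate resamples ``sample_size`` loci (with replacement by
    default), concatenates them and fits the branch model; the observed
    difference from the focal class is located within the empirical
    distribution of replicate SC-SI differences. With ``fast`` (default),
    kappa and branch lengths are fixed at the pooled-GR fit and only the
    class omegas are profiled per replicate — the nuisance parameters are
    common to all replicates by construction.
    """
    tree = tree or LabeledTree()
    if not replace and sample_size > len(gr_alignments):
        raise ValueError(
            f"sample_size {sample_size} exceeds {len(gr_alignments)} loci for "
            "sampling without replacement")
    rng = np.random.default_rng(seed)
    fixed = starts = None
    if fast:
        pool = concatenate(gr_alignments, new_id="GR_pool")
        pool_fit = fit_branch_model(pool, tree, scheme)
        fixed = {"kappa": pool_fit.params.kappa, "lengths": pool_fit.branch_lengths}
        # replicates differ little from the pool: one warm start suffices
        starts = (dict(pool_fit.params.omega_by_class),)
    diffs = np.empty(n_reps)
    idx = np.arange(len(gr_alignments))
    for r in range(n_reps):
        chosen = rng.choice(idx, size=sample_size, replace=replace)
        cat = concatenate([gr_alignments[i] for i in chosen], new_id=f"boot{r}")
        fit = fit_branch_model(cat, tree, scheme, fixed=fixed,
                               omega_starts=starts or (0.1, 1.0, 2.0))
        w = fit.params.omega_by_class
        diffs[r] = w["SC"] - w["SI"]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    percentile = float(100.0 * np.mean(diffs <= observed_diff))
    return BootstrapNull(n_reps, sample_size, diffs, (float(lo), float(hi)),
                         float(observed_diff), percentile)


def expression_regression(records: pd.DataFrame, omega_col: str = "omega",
                          tpm_col: str = "mean_expr", class_col: str = "broad"):
    """OLS of sqrt(dN/dS) on mean TPM, class and their interaction.

    Returns (fit, anova_table, slopes): a sequential (type I) ANOVA table
    and per-class TPM slopes with 95% CIs.
    """
    df = records[[omega_col, tpm_col, class_col]].dropna().copy()
    df["sqrt_omega"] = np.sqrt(df[omega_col].astype(float))
    df = df.rename(columns={tpm_col: "tpm", class_col: "cls"})
    fit = ols("sqrt_omega ~ tpm * C(cls)", data=df).fit()
    anova = anova_lm(fit, typ=1)
    slopes = {}
    params, cov = fit.params, fit.cov_params()
    base_slope = params["tpm"]
    classes = sorted(df["cls"].unique())
    for cls in classes:
        term = f"tpm:C(cls)[T.{cls}]"
        if term in params.index:
            slope = base_slope + params[term]
            var = (cov.loc["tpm", "tpm"] + cov.loc[term, term]
                   + 2 * cov.loc["tpm", term])
        else:
            slope, var = base_slope, cov.loc["tpm", "tpm"]
        se = np.sqrt(var)
        slopes[cls] = {"slope": float(slope),
                       "ci_low": float(slope - 1.96 * se),
                       "ci_high": float(slope + 1.96 * se)}
    return fit, anova, slopes
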