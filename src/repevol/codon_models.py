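"""GY94 codon substitution models on the fixed 4-taxon tree.

Implements the Goldman-Yang style codon model: a 61x61 reversible rate matrix
parameterized by the transition/transversion ratio kappa, the
nonsynonymous/synonymous rate ratio omega (dN/dS), and stationary codon
frequencies (F3x4 by default). Likelihoods are computed by Felsenstein
pruning over site patterns; the one-ratio (M0) model shares a single omega
across all branches while branch models give each pre-labeled branch class
(SC tips, SI tips, internal) its own omega. Nested models are compared by
likelihood-ratio tests against a chi-square reference.

A Nei-Gojobori (1986) pathway-counting estimator is included as an
independent, likelihood-free check on the ML machinery.
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .genetics import (
    CODON_AA,
    CODON_INDEX,
    IS_SYNONYMOUS,
    IS_TRANSITION,
    N_CODONS,
    SINGLE_STEP,
    STOP_CODONS,
    f3x4_frequencies,
    uniform_frequencies,
)
from .tree import BRANCH_NAMES, LabeledTree

logger = logging.getLogger(__name__)

M0 = "M0"
TWO_RATIO = "TWO_RATIO"
THREE_RATIO = "THREE_RATIO"

# Optimization bounds (natural scale).
OMEGA_BOUNDS = (1e-4, 99.0)
KAPPA_BOUNDS = (0.1, 50.0)
LENGTH_BOUNDS = (1e-7, 10.0)
#: Fixed omega start grid making fits deterministic.
OMEGA_STARTS = (0.1, 1.0, 2.0)


class ModelConfigError(ValueError):
    """Model parameterization inconsistent with the requested branch class."""


@dataclass
class CodonModelParams:
    """Parameters of a (possibly branch-heterogeneous) GY94 model."""

    kappa: float
    omega_by_class: dict[str, float]
    codon_freqs: np.ndarray

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (N_CODONS,):
            raise ModelConfigError("codon_freqs must have 61 entries")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-12:
            raise ModelConfigError("codon frequencies must sum to 1")
        if self.kappa <= 0 or any(w < 0 for w in self.omega_by_class.values()):
            raise ModelConfigError("kappa must be > 0 and omegas >= 0")

    def omega_for(self, branch_class: str) -> float:
        try:
            return self.omega_by_class[branch_class]
        except KeyError:
            raise ModelConfigError(
                f"no omega configured for branch class {branch_class!r} "
                f"(have {sorted(self.omega_by_class)})"
            ) from None


@dataclass
class OmegaFit:
    """Result of an ML codon-model fit."""

    locus_or_class_id: str
    model: str
    params: CodonModelParams
    branch_lengths: dict[str, float]
    lnL: float
    dN: float
    dS: float
    dn_ds: float | dict[str, float]
    converged: bool
    notes: list[str] = field(default_factory=list)

    @property
    def tree_length(self) -> float:
        return sum(self.branch_lengths.values())


@dataclass
class LRTResult:
    stat: float
    df: int
    p_value: float


def _flux_components(kappa: float, freqs: np.ndarray) -> tuple[float, float]:
    """Nonsynonymous and synonymous equilibrium flux at omega = 1.

    Returns (A, B) with A = sum over nonsynonymous single-step pairs of
    pi_i * pi_j * kappa^[transition], B the synonymous analogue. The total
    flux at omega w is then w*A + B.
    """
    rate = np.where(IS_TRANSITION, kappa, 1.0) * SINGLE_STEP
    weighted = freqs[:, None] * rate * freqs[None, :]
    a = weighted[SINGLE_STEP & ~IS_SYNONYMOUS].sum()
    b = weighted[SINGLE_STEP & IS_SYNONYMOUS].sum()
    return float(a), float(b)


def build_rate_matrix(params: CodonModelParams, branch_class: str) -> np.ndarray:
    """Scaled GY94 rate matrix for one branch class.

    Off-diagonal rates are pi_j (synonymous transversion), kappa*pi_j
    (synonymous transition), omega*pi_j / kappa*omega*pi_j (nonsynonymous
    transversion / transition) for single-nucleotide changes and 0 otherwise.
    The matrix is scaled so the expected number of substitutions per codon
    per unit branch length is 1 at these parameters.
    """
    omega = params.omega_for(branch_class)
    freqs = params.codon_freqs
    q = np.where(IS_TRANSITION, params.kappa, 1.0) * SINGLE_STEP * freqs[None, :]
    q = np.where(IS_SYNONYMOUS | ~SINGLE_STEP, q, q * omega)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    a, b = _flux_components(params.kappa, freqs)
    scale = omega * a + b
    if scale <= 0:
        raise ModelConfigError("degenerate rate matrix (zero total flux)")
    return q / scale


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); entries clipped at 0, rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    p = linalg.expm(Q * t)
    if not np.all(np.isfinite(p)):
        raise FloatingPointError("non-finite transition probabilities")
    return np.clip(p, 0.0, None)


class _Spectral:
    """Eigendecomposition of a reversible Q for cheap repeated P(t)."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        d = np.sqrt(freqs)
        sym = Q * (d[:, None] / d[None, :])
        sym = 0.5 * (sym + sym.T)
        self.w, v = np.linalg.eigh(sym)
        self.U = v / d[:, None]
        self.W = v * d[:, None]

    def P(self, t: float) -> np.ndarray:
        p = (self.U * np.exp(self.w * t)) @ self.W.T
        return np.clip(p, 0.0, None)


def _branch_P(params: CodonModelParams, tree: LabeledTree, scheme: str,
              lengths: dict[str, float]) -> dict[str, np.ndarray]:
    classes = dict(zip(BRANCH_NAMES, tree.merged_classes(scheme)))
    spectral = {
        cls: _Spectral(build_rate_matrix(params, cls), params.codon_freqs)
        for cls in set(classes.values())
    }
    return {name: spectral[classes[name]].P(lengths[name]) for name in BRANCH_NAMES}


def _pattern_loglik(patterns: np.ndarray, counts: np.ndarray,
                    P: dict[str, np.ndarray], freqs: np.ndarray) -> float:
    """Felsenstein pruning on ((A,B),(C,D)), root on the internal branch."""
    a, b, c, d = (patterns[:, k] for k in range(4))
    upper = P["A"][:, a] * P["B"][:, b]
    lower = P["C"][:, c] * P["D"][:, d]
    site = freqs @ (upper * (P["internal"] @ lower))
    return float(counts @ np.log(np.maximum(site, 1e-300)))


def log_likelihood(aln: CodonAlignment, tree: LabeledTree, params: CodonModelParams,
                   scheme: str = M0) -> float:
    """Log-likelihood of the alignment under the given parameters.

    The root is placed at the internal node adjacent to the SC cherry with
    the internal branch carrying its full length; under the reversible model
    the placement does not affect the likelihood.
    """
    if tuple(aln.taxa) != tuple(tree.taxa):
        raise ValueError(f"alignment taxa {aln.taxa} do not match tree taxa {tree.taxa}")
    patterns, counts = aln.pattern_counts()
    if patterns.size and (patterns.min() < 0 or patterns.max() >= N_CODONS):
        raise ValueError(f"{aln.locus_id}: unrecognized codon state in alignment")
    P = _branch_P(params, tree, scheme, tree.branch_lengths)
    return _pattern_loglik(patterns, counts, P, params.codon_freqs)


def estimate_frequencies(aln: CodonAlignment, scheme: str = "F3x4") -> np.ndarray:
    """Stationary codon frequencies from the data (F3x4, F61 or uniform)."""
    if scheme == "uniform":
        return uniform_frequencies()
    if scheme == "F3x4":
        return f3x4_frequencies(aln.sequence(t) for t in aln.taxa)
    if scheme == "F61":
        counts = np.bincount(aln.codons.ravel(), minlength=N_CODONS).astype(float)
        counts = np.maximum(counts, 1e-6)
        return counts / counts.sum()
    raise ModelConfigError(f"unknown frequency scheme {scheme!r}")


def _dnds_decomposition(kappa: float, freqs: np.ndarray,
                        omega_by_branch: dict[str, float],
                        lengths: dict[str, float]) -> tuple[float, float]:
    """Partition tree length into per-site dN and dS (codeml convention).

    With the scaled matrix, a branch of length t accrues t substitutions per
    codon; the nonsynonymous share is wA/(wA+B). Dividing each share by
    three times the corresponding proportion of sites (computed at omega=1)
    gives substitutions per nonsynonymous / synonymous site, so the per
    branch ratio dN/dS recovers that branch's omega exactly.
    """
    a, b = _flux_components(kappa, freqs)
    f_n, f_s = a / (a + b), b / (a + b)
    dn = ds = 0.0
    for name, t in lengths.items():
        w = omega_by_branch[name]
        rho_n = w * a / (w * a + b)
        dn += t * rho_n / (3 * f_n)
        ds += t * (1 - rho_n) / (3 * f_s)
    return dn, ds


def _initial_lengths(aln: CodonAlignment) -> np.ndarray:
    """Rough starting branch lengths from codon p-distances."""
    p = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        p[i, j] = p[j, i] = np.mean(aln.codons[i] != aln.codons[j])
    tip = np.array([p[0, 1] / 2, p[0, 1] / 2, p[2, 3] / 2, p[2, 3] / 2])
    across = np.mean([p[0, 2], p[0, 3], p[1, 2], p[1, 3]])
    internal = max(across - p[0, 1] / 2 - p[2, 3] / 2, 0.0)
    init = np.concatenate([tip, [internal]]) + 1e-3
    return np.clip(init, *LENGTH_BOUNDS)


def _maximize(aln: CodonAlignment, tree: LabeledTree, scheme: str,
              class_names: list[str], freqs: np.ndarray,
              omega_starts=OMEGA_STARTS, fixed: dict | None = None):
    """Shared optimizer: L-BFGS-B in log-parameter space, fixed start grid.

    ``fixed`` may pin ``kappa`` and/or ``lengths`` (dict), leaving only the
    class omegas free (used by the fast bootstrap path).
    """
    patterns, counts = aln.pattern_counts()
    fixed = fixed or {}
    fix_kappa = fixed.get("kappa")
    fix_lengths = fixed.get("lengths")
    k = len(class_names)

    def unpack(x):
        pos = 0
        if fix_kappa is None:
            kappa = np.exp(x[pos]); pos += 1
        else:
            kappa = fix_kappa
        omegas = dict(zip(class_names, np.exp(x[pos:pos + k]))); pos += k
        if fix_lengths is None:
            lengths = dict(zip(BRANCH_NAMES, np.exp(x[pos:pos + 5])))
        else:
            lengths = fix_lengths
        return kappa, omegas, lengths

    branch_class = dict(zip(BRANCH_NAMES, tree.merged_classes(scheme)))
    spectral_cache: dict[tuple[float, float], _Spectral] = {}

    def _spectral(kappa: float, omega: float) -> _Spectral:
        # finite-difference evals mostly perturb branch lengths, leaving
        # every Q unchanged; cache decompositions by (kappa, omega)
        key = (kappa, omega)
        if key not in spectral_cache:
            if len(spectral_cache) > 512:
                spectral_cache.clear()
            params = CodonModelParams(kappa, {"_": omega}, freqs)
            spectral_cache[key] = _Spectral(build_rate_matrix(params, "_"), freqs)
        return spectral_cache[key]

    def nll(x):
        kappa, omegas, lengths = unpack(x)
        P = {name: _spectral(kappa, omegas[branch_class[name]]).P(lengths[name])
             for name in BRANCH_NAMES}
        return -_pattern_loglik(patterns, counts, P, freqs)

    bounds, base = [], []
    if fix_kappa is None:
        bounds.append(tuple(np.log(KAPPA_BOUNDS)))
        base.append(np.log(2.0))
    bounds += [tuple(np.log(OMEGA_BOUNDS))] * k
    if fix_lengths is None:
        bounds += [tuple(np.log(LENGTH_BOUNDS))] * 5
        t0 = np.log(_initial_lengths(aln))
    best = None
    for w0 in omega_starts:
        # a start may be a scalar (shared by all classes) or a per-class map
        if isinstance(w0, dict):
            ws = [np.log(w0[c]) for c in class_names]
        else:
            ws = [np.log(w0)] * k
        x0 = list(base) + ws
        if fix_lengths is None:
            x0 += list(t0)
        res = optimize.minimize(nll, np.array(x0), method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    kappa, omegas, lengths = unpack(best.x)
    params = CodonModelParams(kappa, omegas, freqs)
    return params, lengths, -float(best.fun), bool(best.success)


def _is_invariant(aln: CodonAlignment) -> bool:
    return bool(np.all(aln.codons == aln.codons[0]))


def fit_m0(aln: CodonAlignment, tree: LabeledTree | None = None,
           freq_scheme: str = "F3x4", omega_starts=OMEGA_STARTS) -> OmegaFit:
    """One-ratio (M0) fit: single omega shared by all five branches.

    Jointly maximizes the likelihood over kappa, omega and the five branch
    lengths from a fixed omega start grid; alignments with four identical
    sequences are flagged degenerate (dN = dS = 0, omega undefined).
    """
    tree = tree or LabeledTree()
    freqs = estimate_frequencies(aln, freq_scheme)
    if _is_invariant(aln):
        params = CodonModelParams(2.0, {"ALL": 1.0}, freqs)
        lnl = float(np.log(freqs[aln.codons[0]]).sum())
        return OmegaFit(aln.locus_id, M0, params, dict.fromkeys(BRANCH_NAMES, 0.0),
                        lnl, 0.0, 0.0, float("nan"), True, ["degenerate"])
    params, lengths, lnl, ok = _maximize(aln, tree, "M0", ["ALL"], freqs, omega_starts)
    omega = params.omega_by_class["ALL"]
    dn, ds = _dnds_decomposition(params.kappa, freqs,
                                 dict.fromkeys(BRANCH_NAMES, omega), lengths)
    notes = []
    if ds < 1e-8:
        notes.append("dS_zero")
    if not ok:
        notes.append("not_converged")
    return OmegaFit(aln.locus_id, M0, params, lengths, lnl, dn, ds, omega, ok, notes)


def fit_branch_model(aln: CodonAlignment, tree: LabeledTree | None = None,
                     scheme: str = THREE_RATIO, freq_scheme: str = "F3x4",
                     omega_starts=OMEGA_STARTS, fixed: dict | None = None) -> OmegaFit:
    """Branch-model fit with class-specific omegas.

    ``THREE_RATIO`` estimates separate omegas for SC tips, SI tips and the
    internal branch; ``TWO_RATIO`` pools the internal branch with SI. Shared
    kappa and branch lengths. ``fixed`` can pin kappa and branch lengths
    (e.g. to a pooled fit) so only the omegas are profiled.
    """
    if scheme not in (TWO_RATIO, THREE_RATIO):
        raise ModelConfigError(f"scheme must be TWO_RATIO or THREE_RATIO, got {scheme!r}")
    tree = tree or LabeledTree()
    freqs = estimate_frequencies(aln, freq_scheme)
    class_names = sorted(set(tree.merged_classes(scheme)))
    if _is_invariant(aln):
        params = CodonModelParams(2.0, dict.fromkeys(class_names, 1.0), freqs)
        lnl = float(np.log(freqs[aln.codons[0]]).sum())
        return OmegaFit(aln.locus_id, scheme, params, dict.fromkeys(BRANCH_NAMES, 0.0),
                        lnl, 0.0, 0.0, dict.fromkeys(class_names, float("nan")),
                        True, ["degenerate"])
    params, lengths, lnl, ok = _maximize(aln, tree, scheme, class_names, freqs,
                                         omega_starts, fixed=fixed)
    merged = dict(zip(BRANCH_NAMES, tree.merged_classes(scheme)))
    omega_by_branch = {name: params.omega_by_class[merged[name]] for name in BRANCH_NAMES}
    dn, ds = _dnds_decomposition(params.kappa, freqs, omega_by_branch, lengths)
    notes = [] if ok else ["not_converged"]
    return OmegaFit(aln.locus_id, scheme, params, lengths, lnl, dn, ds,
                    dict(params.omega_by_class), ok, notes)


def lrt(lnL_null: float, lnL_alt: float, df: int) -> LRTResult:
    """Likelihood-ratio test: 2*(lnL_alt - lnL_null) vs chi-square(df)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < -1e-6:
        logger.warning("alternative lnL below null by %.3g; statistic clipped to 0", -stat)
    stat = max(stat, 0.0)
    return LRTResult(stat, df, float(chi2.sf(stat, df)))


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) pathway counting
# ---------------------------------------------------------------------------

_NUC_ALTS = {"T": "CAG", "C": "TAG", "A": "TCG", "G": "TCA"}


@functools.lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) sites of one codon.

    Changes creating stop codons are excluded from the opportunity counts.
    """
    syn = nonsyn = 0.0
    aa = CODON_AA[CODON_INDEX[codon]]
    for pos in range(3):
        alts = [codon[:pos] + n + codon[pos + 1:] for n in _NUC_ALTS[codon[pos]]]
        valid = [c for c in alts if c not in STOP_CODONS]
        if not valid:
            continue
        frac = 1.0 / len(alts)
        for c in valid:
            if CODON_AA[CODON_INDEX[c]] == aa:
                syn += frac
            else:
                nonsyn += frac
    return syn, nonsyn


@functools.lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) difference counts between two codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are discarded and the remainder weighted equally.
    """
    positions = [k for k in range(3) if c1[k] != c2[k]]
    if not positions:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(positions):
        cur, syn, nonsyn, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_AA[CODON_INDEX[cur]] == CODON_AA[CODON_INDEX[nxt]]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:  # every pathway hits a stop; count all changes nonsynonymous
        return 0.0, float(len(positions))
    arr = np.array(totals, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def _jukes_cantor(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * np.log(arg)


def ng86_counting(seq1: str, seq2: str) -> dict:
    """NG86 dN/dS for a pair of equal-length, gap-free codon sequences.

    Returns {"dN", "dS", "dn_ds", "estimable", "S", "N", "Sd", "Nd"}.
    Sites are averaged between the two sequences; multi-difference codons
    average over equally weighted mutational pathways; proportions are
    Jukes-Cantor corrected. Saturated divergence is flagged not estimable.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("sequences must be equal-length in-frame codon strings")
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        ds_i, dn_i = _pathway_diffs(c1, c2)
        sd += ds_i
        nd += dn_i
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    d_s = _jukes_cantor(ps)
    d_n = _jukes_cantor(pn)
    estimable = d_s is not None and d_n is not None
    ratio = float("nan")
    if estimable:
        ratio = d_n / d_s if d_s > 0 else (0.0 if d_n == 0 else float("inf"))
    return {"dN": d_n if d_n is not None else float("nan"),
            "dS": d_s if d_s is not None else float("nan"),
            "dn_ds": ratio, "estimable": estimable,
            "S": s_sites, "N": n_sites, "Sd": sd, "Nd": nd}
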