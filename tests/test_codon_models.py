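"""Codon model engine: rate matrices, pruning likelihood, ML fits, NG86."""

import itertools

import numpy as np
import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.linalg import expm
from scipy.stats import spearmanr

import repevol as rv
from repevol.alignment import CodonAlignment
from repevol.codon_models import (
    ModelConfigError,
    OMEGA_STARTS,
    estimate_frequencies,
    ng86_counting,
)
from repevol.genetics import (
    CODON_INDEX,
    N_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
    uniform_frequencies,
)
from repevol.tree import BRANCH_NAMES, LabeledTree

from conftest import simulate_locus

# ---------------------------------------------------------------------------
# independent oracles, built from Biopython translation only
# ---------------------------------------------------------------------------

_PURINES = set("AG")


def oracle_rate_matrix(kappa, omega, freqs):
    """GY94 rate matrix built by direct enumeration, unscaled."""
    q = np.zeros((N_CODONS, N_CODONS))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            (k,) = diffs
            rate = freqs[j]
            if (ci[k] in _PURINES) == (cj[k] in _PURINES):
                rate *= kappa
            if Seq(ci).translate() != Seq(cj).translate():
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def oracle_loglik(aln, tree, params, scheme="M0", split_root=False):
    """Brute-force likelihood: explicit sum over both internal node states.

    With ``split_root`` the root is placed at the midpoint of the internal
    branch (three internal nodes) to exercise the pulley principle.
    """
    classes = dict(zip(BRANCH_NAMES, tree.merged_classes(scheme)))
    lengths = tree.branch_lengths
    freqs = params.codon_freqs

    def P(name, t=None):
        w = params.omega_by_class[classes[name]]
        q = oracle_rate_matrix(params.kappa, w, freqs)
        a, b = 0.0, 0.0
        # rescale exactly as advertised: expected substitutions/codon = 1
        scale = -(freqs * np.diag(q)).sum()
        return expm(q / scale * (lengths[name] if t is None else t))

    PA, PB, PC, PD = (P(n) for n in "ABCD")
    total = 0.0
    for col in aln.codons.T:
        a, b, c, d = (int(x) for x in col)
        site = 0.0
        if not split_root:
            PI = P("internal")
            for u in range(N_CODONS):
                for v in range(N_CODONS):
                    site += (freqs[u] * PA[u, a] * PB[u, b]
                             * PI[u, v] * PC[v, c] * PD[v, d])
        else:
            PH = P("internal", lengths["internal"] / 2)
            for r in range(N_CODONS):
                up = sum(PH[r, u] * PA[u, a] * PB[u, b] for u in range(N_CODONS))
                low = sum(PH[r, v] * PC[v, c] * PD[v, d] for v in range(N_CODONS))
                site += freqs[r] * up * low
        total += np.log(site)
    return total


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kappa,omega", [(1.0, 1.0), (2.5, 0.3), (7.0, 2.0)])
def test_rate_matrix_properties(kappa, omega):
    params = rv.CodonModelParams(kappa, {"ALL": omega}, uniform_frequencies())
    Q = rv.build_rate_matrix(params, "ALL")
    pi = params.codon_freqs
    flux = pi[:, None] * Q
    assert np.allclose(flux, flux.T, atol=1e-14), "detailed balance"
    assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
    assert np.isclose(-(pi * np.diag(Q)).sum(), 1.0), "unit substitution rate"


def test_omega_zero_kills_nonsynonymous_rates():
    params = rv.CodonModelParams(3.0, {"ALL": 0.0}, uniform_frequencies())
    Q = rv.build_rate_matrix(params, "ALL")
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i != j and Seq(ci).translate() != Seq(cj).translate():
                assert Q[i, j] == 0.0


def test_neutral_symmetric_matrix_is_adjacency():
    params = rv.CodonModelParams(1.0, {"ALL": 1.0}, uniform_frequencies())
    Q = rv.build_rate_matrix(params, "ALL")
    off = Q[~np.eye(N_CODONS, dtype=bool)]
    adj = np.array([
        sum(a != b for a, b in zip(ci, cj)) == 1
        for ci in SENSE_CODONS for cj in SENSE_CODONS if ci != cj
    ])
    nz = off[adj]
    assert np.allclose(nz, nz[0]), "single-step rates all equal"
    assert np.all(off[~adj] == 0)


def test_missing_branch_class_omega_errors():
    params = rv.CodonModelParams(2.0, {"SC": 0.5}, uniform_frequencies())
    with pytest.raises(ModelConfigError):
        rv.build_rate_matrix(params, "SI")


# ---------------------------------------------------------------------------
# transition probabilities
# ---------------------------------------------------------------------------

def test_transition_probs_limits_and_chapman_kolmogorov():
    params = rv.CodonModelParams(2.0, {"ALL": 0.4}, uniform_frequencies())
    Q = rv.build_rate_matrix(params, "ALL")
    assert np.allclose(rv.transition_probs(Q, 0.0), np.eye(N_CODONS), atol=1e-12)
    P_long = rv.transition_probs(Q, 500.0)
    assert np.allclose(P_long, np.tile(params.codon_freqs, (N_CODONS, 1)), atol=1e-8)
    P1, P2 = rv.transition_probs(Q, 0.3), rv.transition_probs(Q, 0.7)
    assert np.allclose(rv.transition_probs(Q, 1.0), P1 @ P2, atol=1e-8)
    assert np.allclose(rv.transition_probs(Q, 0.5).sum(axis=1), 1.0, atol=1e-10)
    with pytest.raises(ValueError):
        rv.transition_probs(Q, -0.1)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_single_codon_zero_lengths_likelihood_is_log_pi():
    aln = CodonAlignment("one", ("a", "b", "c", "d"),
                         np.full((4, 1), CODON_INDEX["ATG"]))
    tree = LabeledTree(taxa=("a", "b", "c", "d"), lengths=(0,) * 5)
    params = rv.CodonModelParams(2.0, {"ALL": 0.5}, uniform_frequencies())
    ll = rv.log_likelihood(aln, tree, params)
    assert np.isclose(ll, np.log(params.codon_freqs[CODON_INDEX["ATG"]]))


@pytest.mark.parametrize("scheme,omegas", [
    ("M0", {"ALL": 0.4}),
    ("THREE_RATIO", {"SC": 0.6, "SI": 0.2, "INTERNAL": 1.1}),
])
def test_pruning_matches_brute_force(scheme, omegas):
    aln = simulate_locus(11, n_codons=2,
                         lengths={"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.15,
                                  "internal": 0.25})
    tree = LabeledTree(lengths=(0.1, 0.2, 0.3, 0.15, 0.25))
    params = rv.CodonModelParams(2.5, omegas, uniform_frequencies())
    got = rv.log_likelihood(aln, tree, params, scheme=scheme)
    want = oracle_loglik(aln, tree, params, scheme=scheme)
    assert abs(got - want) < 1e-8


def test_root_placement_on_internal_branch_is_irrelevant():
    aln = simulate_locus(13, n_codons=3,
                         lengths={"A": 0.05, "B": 0.1, "C": 0.2, "D": 0.12,
                                  "internal": 0.3})
    tree = LabeledTree(lengths=(0.05, 0.1, 0.2, 0.12, 0.3))
    params = rv.CodonModelParams(3.0, {"ALL": 0.7}, uniform_frequencies())
    at_node = rv.log_likelihood(aln, tree, params)
    at_midpoint = oracle_loglik(aln, tree, params, split_root=True)
    assert abs(at_node - at_midpoint) < 1e-8


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def test_fit_m0_identical_sequences_flagged_degenerate():
    row = np.array([[CODON_INDEX["ATG"], CODON_INDEX["AAA"], CODON_INDEX["TGG"]]] * 4)
    aln = CodonAlignment("ident", LabeledTree().taxa, row)
    fit = rv.fit_m0(aln)
    assert fit.dN == 0 and fit.dS == 0
    assert "degenerate" in fit.notes
    assert np.isnan(fit.dn_ds)


def test_fit_m0_dnds_decomposition_consistent():
    aln = simulate_locus(21, n_codons=400, omegas={"SC": 0.5, "SI": 0.5, "INTERNAL": 0.5})
    fit = rv.fit_m0(aln)
    assert fit.converged
    assert fit.dN >= 0 and fit.dS >= 0
    assert np.isclose(fit.dN / fit.dS, fit.dn_ds, rtol=1e-8)


def test_fit_m0_rank_agrees_with_ng86_counting():
    """ML omega and the counting estimator order loci the same way."""
    rng = np.random.default_rng(5)
    ml, counting = [], []
    for i in range(20):
        w = [0.1, 0.5, 1.5][i % 3]
        aln = simulate_locus(int(rng.integers(2**31)), n_codons=300,
                             omegas={"SC": w, "SI": w, "INTERNAL": w})
        ml.append(rv.fit_m0(aln).dn_ds)
        ratios = []
        for a, b in itertools.combinations(aln.taxa, 2):
            res = ng86_counting(aln.sequence(a), aln.sequence(b))
            if res["estimable"] and np.isfinite(res["dn_ds"]) and res["dS"] > 0:
                ratios.append(res["dn_ds"])
        counting.append(np.mean(ratios))
    rho = spearmanr(ml, counting).statistic
    assert rho > 0.8


def test_nested_model_log_likelihood_ordering():
    aln = simulate_locus(31, n_codons=200)
    tree = LabeledTree()
    l0 = rv.fit_m0(aln, tree).lnL
    l2 = rv.fit_branch_model(aln, tree, rv.TWO_RATIO).lnL
    l3 = rv.fit_branch_model(aln, tree, rv.THREE_RATIO).lnL
    assert l3 >= l2 - 1e-6 >= l0 - 2e-6


# ---------------------------------------------------------------------------
# LRT
# ---------------------------------------------------------------------------

def test_lrt_identical_likelihoods_and_clipping():
    res = rv.lrt(-100.0, -100.0, 2)
    assert res.stat == 0.0 and res.p_value == 1.0
    res = rv.lrt(-100.0, -100.5, 1)  # optimizer noise: clipped, not negative
    assert res.stat == 0.0
    with pytest.raises(ValueError):
        rv.lrt(-10.0, -9.0, 0)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def test_ng86_identical_sequences():
    res = ng86_counting("ATGAAA", "ATGAAA")
    assert res["dN"] == 0 and res["dS"] == 0 and res["estimable"]


def test_ng86_single_synonymous_difference():
    s1 = "AAA" * 99 + "TTA"
    s2 = "AAA" * 99 + "TTG"  # Leu -> Leu, synonymous
    res = ng86_counting(s1, s2)
    assert res["dN"] == 0 and res["dS"] > 0 and res["dn_ds"] == 0


def _oracle_pathways(c1, c2):
    """Exhaustive pathway listing, written independently of the package."""
    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    positions = [k for k in range(3) if c1[k] != c2[k]]
    outcomes = []
    for order in itertools.permutations(positions):
        cur, sy, ns = c1, 0, 0
        alive = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                alive = False
                break
            if table[cur] == table[nxt]:
                sy += 1
            else:
                ns += 1
            cur = nxt
        if alive:
            outcomes.append((sy, ns))
    return outcomes


def test_ng86_multi_difference_codon_matches_pathway_oracle():
    # TTT (Phe) -> GTA (Val): 3 differences, 6 pathways, some through stops
    s1, s2 = "ATG" + "TTT" + "AAA", "ATG" + "GTA" + "AAA"
    res = ng86_counting(s1, s2)
    outcomes = _oracle_pathways("TTT", "GTA")
    sd = np.mean([o[0] for o in outcomes])
    nd = np.mean([o[1] for o in outcomes])
    assert np.isclose(res["Sd"], sd) and np.isclose(res["Nd"], nd)


def test_ng86_saturation_flagged():
    # maximally divergent: every codon differs everywhere -> JC blows up
    s1 = "AAA" * 30
    s2 = "GGG" * 30
    res = ng86_counting(s1, s2)
    assert not res["estimable"]


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def test_concatenate_lengths_identity_and_errors():
    a = simulate_locus(41, n_codons=100, locus_id="a")
    b = simulate_locus(42, n_codons=100, locus_id="b")
    cat = rv.concatenate([a, b])
    assert cat.n_codons == 200
    assert cat.boundaries == [("a", 100), ("b", 100)]
    single = rv.concatenate([a])
    assert np.array_equal(single.codons, a.codons)
    bad = CodonAlignment("bad", ("w", "x", "y", "z"), a.codons.copy())
    with pytest.raises(Exception, match="bad"):
        rv.concatenate([a, bad])


def test_concatenation_log_likelihood_is_additive():
    a = simulate_locus(43, n_codons=60, locus_id="a")
    b = simulate_locus(44, n_codons=80, locus_id="b")
    tree = LabeledTree()
    params = rv.CodonModelParams(2.0, {"ALL": 0.5}, uniform_frequencies())
    cat = rv.concatenate([a, b])
    assert np.isclose(rv.log_likelihood(cat, tree, params),
                      rv.log_likelihood(a, tree, params)
                      + rv.log_likelihood(b, tree, params))
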