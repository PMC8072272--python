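# Methods

## The codon substitution model

`repevol` implements the Goldman–Yang (GY94) codon model over the 61 sense
codons of the universal code. The instantaneous rate from codon *i* to *j*
is zero unless the codons differ at exactly one nucleotide position, and
otherwise

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous],

where κ > 0 is the transition/transversion rate ratio, ω ≥ 0 the
nonsynonymous/synonymous rate ratio (dN/dS), and π the stationary codon
frequencies. The matrix is rescaled so that −Σ_i π_i q_ii = 1: branch
lengths are expected substitutions per codon at the fitted parameters.
The chain is time-reversible (π_i q_ij = π_j q_ji holds exactly), which the
likelihood machinery exploits: transition probabilities P(t) = exp(Qt) are
computed through the eigendecomposition of the symmetrized matrix
D^{1/2} Q D^{−1/2}, so one decomposition per branch class serves every
branch length visited by the optimizer.

Stationary frequencies default to **F3×4** — products of codon-position
specific nucleotide frequencies estimated from the alignment being fit,
renormalized over sense codons, with a 1e-6 floor so every codon remains
representable. F61 (empirical codon frequencies) and uniform (1/61)
schemes are available by argument.

### Likelihood and tree

The species tree is fixed: the unrooted quartet ((A,B),(C,D)) with A, B the
self-compatible tips, C, D the self-incompatible tips, and one internal
branch. Likelihoods use Felsenstein pruning over unique site patterns with
the root placed at the internal node adjacent to the SC cherry and the
internal branch carrying its full length; under reversibility the placement
is irrelevant (tested against a brute-force computation with the root at
the branch midpoint).

### Fitting

* **M0 (one ratio)**: κ, a single ω, and the five branch lengths are
  maximized jointly.
* **Branch models**: the three-ratio model gives SC tips, SI tips and the
  internal branch separate ω's; the two-ratio model pools the internal
  branch with SI. κ and branch lengths are shared across classes and
  re-estimated per model.

Optimization is bounded L-BFGS-B in log-parameter space with
ω ∈ [1e-4, 99], κ ∈ [0.1, 50], branch lengths ∈ [1e-7, 10], run from a
fixed three-point ω start grid {0.1, 1, 2} (best of the three kept), so
fits are deterministic. Branch lengths start from codon p-distances.
Alignments whose four sequences are identical are flagged degenerate
(dN = dS = 0, ω undefined) without optimization; non-convergent fits are
flagged and excluded downstream.

dN and dS are derived from the fitted tree length by partitioning each
branch's expected substitutions into nonsynonymous and synonymous flux
(ωA/(ωA+B) and its complement, with A and B the equilibrium nonsynonymous
and synonymous flux at ω = 1) and dividing by three times the corresponding
proportions of sites computed at ω = 1; the per-branch ratio dN/dS then
recovers that branch's ω exactly.

The **NG86** counting estimator (fractional synonymous/nonsynonymous sites
per codon, equal weighting of mutational pathways for multi-difference
codons, Jukes–Cantor correction) is implemented purely as an independent
check on the ML machinery. Changes through stop codons are excluded from
site counts and pathways; saturated divergence is flagged not estimable.

## Expression classification

Counts → TPM → per-(species, tissue) replicate means over eight tissues.
The classification thresholds are TPM > 2 ("expressed") and TPM < 0.5
("trace"); labels need agreement from at least two of the three fully
sampled species. Design choices where the rules left room:

* Both conditions of a vote (expression on one side, trace on the other)
  are evaluated **within the same species**; cross-species mixing would let
  discordant species jointly manufacture a label.
* The GR (expressed on both sides) label uses the same ≥ 2-of-3 vote as RP
  and VG.
* In the ploidy partition, style is sporophytic (diploid tissue); pollen and
  ovule are gametophytic.
* Mean expression averages only cells above the 2-TPM threshold (the
  gene's expressed domain) and is 0 for genes expressed nowhere.
* Genes whose values sit between the thresholds (0.5–2 TPM) can fail every
  class; they are UNCLASSIFIED by design.
* Missing (species, tissue) combinations — e.g. style and pollen for
  *S. pimpinellifolium* — are recorded as absent and never imputed; votes
  and breadth computations use only the tissues a species actually has.

## Comparative statistics

* Records with dN/dS > 10 (strict), non-convergent or degenerate fits are
  removed before any comparison, with drop counts logged.
* Class means: gamma GLM with identity link. The gamma support excludes 0
  while real dN/dS data contain zeros; zeros are replaced by half the
  smallest positive value (recorded on the fit, configurable upstream).
* Pairwise contrasts: Wald z statistics with single-step adjustment — the
  adjusted p of contrast k is P(max_j |Z_j| ≥ |z_k|) under the joint normal
  law of the contrast vector, estimated by Monte Carlo (2×10⁵ draws, fixed
  seed). A compact letter display summarizes significance at α = 0.05.
* Proportions of loci with dN/dS > 1: Pearson chi-square (no continuity
  correction) across classes; one-sided Fisher's exact tests for directed
  enrichment of a named class.
* Bootstrap SC−SI null: each replicate resamples loci **with replacement**
  (the without-replacement variant is available) from the GR pool,
  concatenates and refits the branch model (three-ratio by default). By
  default replicate fits profile only the class ω's with κ and branch
  lengths fixed at the pooled-GR fit — those nuisance parameters are common
  to all replicates by construction — which cuts per-replicate cost by an
  order of magnitude; a full refit per replicate is available
  (``fast=False``).
* Expression regression: OLS of sqrt(dN/dS) on mean TPM × class with a
  sequential (type I) ANOVA table and per-class slopes with 95% CIs.

## The synthetic-data generator

Sequence side: alignments are evolved forward along the labeled tree — root
codons drawn from the stationary law, each branch applying its class
transition matrix. Defaults: κ = 2, ω = 0.3 on all branch classes, uniform
codon frequencies, and branch lengths SC tips 0.002, SI tips 0.02, internal
0.01 substitutions/codon — an illustrative echo of the strong SC-short /
SI-long asymmetry between these lineages, not an estimate.

Expression side: each planted RP/VG gene expresses one focal tissue at
50 TPM with 0.05 TPM background; GR genes express one tissue on each side.
A housekeeping pool (100 genes, expressed in all eight tissues — genuinely
GR) absorbs the remainder of each library's 10⁶ TPM budget so planted
values survive renormalization. Counts are negative binomial (dispersion
10 by default, i.e. clearly overdispersed relative to Poisson) with
expected counts proportional to TPM × gene length within a 2×10⁶-read
library; three replicates per species × tissue; style and pollen libraries
are omitted for *S. pimpinellifolium*.

What the generator does **not** emulate: alignment error, indels, selection
heterogeneity among sites, isoform structure, GC-content variation in codon
frequencies, batch effects, and library-size variation. Tests passing on
these data show the estimators and rules behave correctly under the model's
own assumptions; they do not certify robustness to real-data artifacts.

## Problem sizes used by the test suite

Simulation checks are sized to be statistically decisive while keeping the
default suite practical on a single CPU:

* M0 ω recovery: 30 replicates × 500 codons at ω ∈ {0.1, 0.5, 1.0}, on the
  asymmetric tree scaled ×3 (SC 0.006 / SI 0.06 / internal 0.03), i.e.
  ~80 substitutions per locus. At the much shorter default lengths a
  500-codon locus carries ~30 events and the ML ratio exhibits the ordinary
  small-sample upward median bias at low ω (it disappears by 2000 codons);
  the benchmark targets the regime where the consistency claim is
  meaningful.
* Branch-model sign recovery: 100 replicates of 50-locus × 500-codon
  concatenations at ω_SC = 0.4 vs ω_SI = 0.2.
* LRT null calibration: 100 null replicates of 2000-codon alignments —
  concatenation-like data, matching how the branch-model LRT is actually
  used; on short single loci the statistic is truncated below its χ²
  reference and the test is conservative.
* Bootstrap null: 10 meta-replicates per arm; each simulates a 300-locus GR
  pool and a 200-locus focal pool of 200-codon loci (SC tips 0.01,
  preserving SC < SI), fits the focal concatenation and bootstraps 100
  replicates of 50 loci. Pools are much larger than the resample so pool-
  level noise does not erode CI coverage — mirroring the study design,
  where the baseline pool dwarfs the resample size. The power arm inflates
  the focal SC ω by +0.15.
* Classification recovery: 1000 planted genes at dispersion 10.
* End-to-end: 360 loci of 120 codons (the study's mean reproductive locus
  is ~122 codons), RP ω inflated by +0.1 on every branch.

## Other design choices

* Per-class concatenations for the branch models use exactly the loci that
  survive the standard per-locus filters (length, convergence, dN/dS ≤ 10);
  no separate inclusion rule is applied, so locus counts reconcile between
  the per-locus and concatenated analyses by construction.
* All randomness in a pipeline run fans out deterministically from the
  single top-level seed (one derived seed per stage), so fixing the seed
  fixes every downstream number including bootstrap replicates and the
  contrast Monte Carlo.

## Known limitations

* The likelihood engine is specialized to the fixed 4-taxon topology; it is
  not a general tree engine (no topology search, no site/branch-site
  models, by design).
* κ and branch lengths are re-estimated per model fit; the bootstrap's fast
  path deliberately holds them at pooled values.
* dN/dS near the ω lower bound (1e-4) and loci with dS = 0 are flagged
  rather than estimated; the > 10 ceiling removes the corresponding
  upper-end artifacts.
* The single-step contrast adjustment is Monte Carlo, exact only up to
  ±~0.002 at the default draw count.
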