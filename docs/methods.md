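# Methods

This note records the models `dupsel` implements, the assumptions and
numerical choices behind them, what the synthetic-data generators do and do
not emulate, and the package's known limitations.

## Codon alignments and gap policy

All evolutionary computations run on in-frame codon alignments. Alignment
gaps are removed by *complete deletion at codon granularity*: any codon
column in which any sequence carries a gap, an ambiguous base (N is treated
as a gap, since synonymous/non-synonymous site counting is undefined for
ambiguous codons), or a stop codon is removed whole. Deleting whole codon
columns is the only gap-stripping rule that preserves every sequence's
reading frame. Construction is idempotent and the retained column count
(`n_codons`) is carried on the alignment.

The genetic code is injected (default: the standard nuclear code with 61
sense codons; 2 one-fold, 9 two-fold, 1 three-fold, 5 four-fold and 3
six-fold amino-acid families), so toy codes can be used in tests.

## Pairwise dN/dS (NG86 with Jukes–Cantor correction)

Per codon, each of the three positions contributes a synonymous-site
fraction equal to the proportion of its three single-base mutations that
are synonymous, with mutations creating stop codons excluded from the
denominator (the classic convention, which keeps S + N = 3 exactly per
codon). For a differing codon pair with k differing positions, synonymous
and non-synonymous step counts are averaged over all k! mutational
orderings, excluding pathways that pass through a stop codon; in the
degenerate case where every pathway is blocked, the average is taken over
all pathways with stop steps counted non-synonymous and a warning raised.
Sites S, N are averaged over the two sequences; proportions pS = ΣSd/S and
pN = ΣNd/N are corrected for multiple hits with d = −(3/4)·ln(1 − 4p/3),
which is undefined at p ≥ 3/4 (reported as a saturation error naming the
pair). The per-clade summary reports the mean and *sample* standard
deviation of dN and dS across all sequence pairs; a bootstrap standard
error is not implemented.

## Molecular-clock dating

T = dS / (2K). The default rate K = 4.38e-9 substitutions per site per
year is a mean synonymous rate estimated for tomato-clade loci; it is a
configuration value, not a constant, and should be replaced when dating
divergences outside that clade. The factor 2 reflects that dS accumulates
along both lineages since their split.

## Effective number of codons

Wright's Nc from codon homozygosity: for each amino-acid family,
F = Σ pᵢ² over its synonymous codons (the `raw` estimator; the
`bias_corrected` option uses (nΣpᵢ² − 1)/(n − 1), the small-sample form
used by codon-usage tools). Nc sums, per degeneracy class, the number of
families divided by the class mean F̄; one-fold families contribute their
count (2 under the standard code). Families unobserved (or with n < 2
under the corrected estimator) take the mean F of observed families of the
same class; a wholly unobserved class falls back to the no-bias
expectation F = 1/k, which keeps Nc defined on short sequences. At one
codon per amino acid the formula gives 20 (2 + 9 + 1 + 5 + 3); the value
21 sometimes quoted for maximal bias is not reproduced by the formula and
is not forced. Estimates above 61 (possible under the corrected estimator
on short sequences) are clamped with a flag. Stop codons are never
counted.

## Codon site models

The substitution process is the standard reversible codon model:
instantaneous rates between sense codons differing at one nucleotide are
π_j (synonymous transversion), κπ_j (synonymous transition), ωπ_j and
ωκπ_j (non-synonymous), zero for multi-nucleotide changes. Equilibrium
frequencies default to F3x4 — products of position-specific nucleotide
frequencies renormalized over sense codons, floored at 1e-10 for observed
codons — with a uniform option for testing. Site models mix over ω:

* M0: one ω class (free parameters: ω, plus κ and branch lengths);
* M1a: ω₀ ∈ [0, 1) with proportion p₀, ω₁ = 1 fixed (p₀, ω₀ free);
* M2a: adds ω₂ ≥ 1 with proportion p₂ (p₀, p₁, ω₀, ω₂ free).

Within a model, all class generators share κ and π and are divided by the
mixture-averaged rate, so one unit of branch length is one expected
substitution per codon under the fitted mixture (classes correctly evolve
at different relative speeds). Likelihoods are computed by Felsenstein
pruning over site patterns; transition matrices come from a single
symmetric eigendecomposition of the π-symmetrized generator, which is
stable for the 61-state reversible process.

**Fitting.** Bounded L-BFGS-B over κ ∈ [0.1, 30], branch lengths ∈
[1e-6, 10], ω ∈ [1e-4, 99] (ω₀ capped below 1, ω₂ floored at 1),
proportions parametrized inside the simplex; relative log-likelihood
tolerance 1e-8. The first start is deterministic — or warm-started from
a nested fit when one is passed via `init`, which both speeds the
M0 → M1a → M2a ladder and guarantees the nesting inequality in practice —
followed by seeded random restarts (default 5 total). Branch lengths and κ
are re-estimated per model. The guide tree for three sequences is the
unrooted 3-branch star (the only unrooted topology); more sequences
require an explicit tree, typically the NJ tree from the trees module.
Non-convergence after all restarts returns the best point flagged
`converged=False` rather than raising.

**LRT.** 2Δℓ between nested fits is referred to χ² with df 1 (M1a vs M0)
or df 2 (M2a vs M1a). Slightly negative statistics from optimizer noise
are clamped to zero (warning beyond 1e-6). The M2a-vs-M1a test is
conservative because the null places parameters on the boundary; the test
suite checks its empirical size stays at or below the nominal level.

**BEB.** Positively selected sites are located by Bayes empirical Bayes:
κ, branch lengths and π are fixed at the M2a estimates, and the mixture
parameters are integrated over a discrete uniform prior — (p₀, p₁) on the
midpoint grid of the unit triangle, ω₀ on 10 midpoints of (0, 1), ω₂ on 10
midpoints of (1, 11). Every candidate generator is scaled by the M2a MLE
mixture rate so branch lengths keep their fitted meaning. The reported
quantity is the posterior probability that each codon belongs to the ω₂
class; sites at or above the threshold (default 0.95) are flagged with the
reference sequence's amino acid and 1-based position in the gap-deleted
alignment.

## Distance trees

Distance matrices over aligned sequences use pairwise deletion (gappy
promoter alignments would lose most columns under complete deletion; the
codon modules keep complete deletion — a deliberate difference). Models:
p-distance and Jukes–Cantor. Neighbor joining follows the Saitou–Nei
Q-criterion with ties broken at the lowest index pair (determinism);
negative branch-length estimates are clamped to zero. On an additive
matrix NJ reproduces the generating tree exactly, which the tests verify
by patristic-distance comparison. Bootstrap support resamples alignment
columns with replacement and reports, for each internal bipartition of the
full-data tree, the percentage of replicate trees containing it, stored as
internal node labels. Trees are `dendropy.Tree` objects; newick I/O goes
through dendropy.

## Promoter motif scanning

Motifs are IUPAC consensus strings with fixed-length repeat notation
(`CCW{6}GG`), compiled to regular expressions. Scanning reports all
(overlapping) matches on both strands in forward-strand 0-based half-open
coordinates; minus-strand matches are found by scanning with the
reverse-complemented consensus. A palindromic match covering one span is
reported once, on the plus strand. The default motif set (CArG `CCW{6}GG`,
PBE-box `CACATG`, G-box `CACGTG`, E-box `CANNTG`, ACE `ACGTG`, CA-hybrid
`GACGTA`, CG-hybrid `GACGTG`) ships as a configuration file, not code
constants: the hybrid/ACE consensus strings follow the motif literature's
common short forms and should be validated against the primary references
before biological use. Promoters are taken as 2-kb fragments upstream of
the translation start. No position-weight-matrix scoring is implemented —
matching is exact consensus logic.

## qPCR analysis

Quantification re-implements the window-of-linearity idea: the baseline is
the mean of cycles 1–5 (the original tool's iterative baseline estimation
is deliberately simplified), baseline-corrected fluorescence is fitted in
log10 space over all 4–6-cycle windows with strictly positive values, and
the window maximizing r² wins. Ties — exact on noise-free exponentials —
resolve toward the widest, then latest window, i.e. the highest
signal-to-noise stretch just below the plateau; this anchors Ct against
the plateau so that shifting a curve by c cycles shifts Ct by c, while
rescaling the whole curve leaves the efficiency unchanged. E = 10^slope,
the threshold is the geometric midpoint of the window's fluorescence span,
Ct is the fitted line's crossing of it, and quantity = threshold / E^Ct
(invariant to the window choice on exact exponentials). Efficiencies
outside (1, 2.5] are flagged, not rejected. Precomputed Ct/E tables are
accepted directly with a shared threshold that cancels in normalization.

Technical replicates are combined by geometric mean of quantities;
normalized expression is the target quantity divided by the *arithmetic*
mean of the two reference-gene quantities (geometric available by option;
which of the two a given study used is rarely stated). Fold changes divide
condition means by the baseline condition mean, making the baseline column
identically 1. Group differences use a two-sided permutation test on
|mean difference|: exhaustive over all label reassignments when their
count is at most 20 000 (deterministic, seed-free), otherwise Monte Carlo
with an add-one correction, p = (exceedances + 1)/(m + 1). The pipeline
reports raw per-comparison p-values by default (matching the common
practice of per-comparison testing at 0.05) with optional
Benjamini–Hochberg adjustment.

## Synthetic data generators

* **Codon alignments**: per site, an ω class is drawn from the mixture;
  the root codon is drawn from π and each branch applies the exact
  transition matrix of that site's class (sampling from exp(Qt) rather
  than simulating jump chains — exact and fast at 61 states). True site
  classes and the root sequence are always returned. Defaults (3 taxa,
  500 codons, κ = 2, branch length 0.05, purifying ω = 0.3) produce
  pairwise synonymous distances in the 0.04–0.16 range typical of
  recently duplicated plant paralogs.
* **qPCR**: target Ct = base − log_E(fold change) + Gaussian noise per
  biological replicate (default sd 0.2 cycles, 3+ replicates); reference
  genes are condition-independent; technical replicates share the
  biological Ct (technical variability is not modelled). Optionally the
  table is embedded into exponential-plus-plateau fluorescence curves.
* **Promoters**: i.i.d. background with planted motif instances realized
  uniformly over each IUPAC code's choices; overlapping plants must agree
  where they intersect, otherwise the generator raises.

What passing tests on these data show — and do not show: the generators
realize exactly the models the estimators assume (no indels, no
recombination, no rate variation beyond ω classes, no alignment error, no
pipetting/plate effects, uniform or F3x4-consistent base composition), so
recovery tests validate the *implementations*, not robustness of the
methods to real-data violations of those assumptions.

## Problem sizes and calibration checks

The empirical size of the M2a-vs-M1a test is checked over 200 alignments
simulated under the nearly-neutral model (400 codons, 3 taxa, single
warm-started fit per model), the permutation test's size over 2000
two-group null datasets (5 replicates per group, exhaustive enumeration),
and ω recovery at 500–1000 codons — sizes chosen to make the checks sharp
while keeping the default suite runnable on a laptop in a few minutes.

## Known limitations

* No branch or branch-site models, no M7/M8, no codon-frequency model
  selection; pairwise distances are NG86-only (no Li–Wu–Luo, no ML
  pairwise).
* Alignment computation is out of scope — alignments are inputs.
* NJ is the only tree method (no ML/Bayesian search); bootstrap supports
  attach to the full-data topology only.
* The BEB grid fixes κ and branch lengths at their M2a estimates; the
  integration covers mixture parameters only.
* Nc imputation for unobserved families is a pragmatic convention;
  comparisons across sequences of very different lengths should use the
  bias-corrected estimator with care.
* The window-of-linearity implementation uses a fixed five-cycle baseline
  window rather than iterative baseline reconstruction.
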