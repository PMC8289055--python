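# Methods

## The convergence-at-conservative-sites caller

The caller operates column-by-column on per-gene protein alignments under
a five-group design: one outgroup *O*, two foreground clusters *P₁, P₂*
(default four taxa each) and two background clusters *A₁, A₂* matched in
size and topology. Two filters are applied in sequence:

1. **Conservativeness.** A column is conservative for the foreground when
   all eight control taxa carry a determinate residue equal to the
   outgroup's. Requiring identity across the whole control side plus the
   outgroup makes mis-inference of the two foreground-cluster ancestral
   states rare (quantified below), so the outgroup residue can stand in
   for both ancestors without probabilistic reconstruction.
2. **Convergence.** Given ancestral state *O*, a convergent substitution
   requires one identical derived residue *d ≠ O* in at least
   `min_shared_per_cluster` taxa of *each* foreground cluster. The
   default 3-of-4 per cluster implements the ≥6-of-8 condition through
   its per-cluster form, which guarantees both clusters contribute
   independent origins of *d*; a pooled ≥6-total-any-split variant is
   available via `support_mode="total"`.

Rules at the margins, chosen where the method description is open:

- Columns with a gapped or unknown outgroup are skipped: the ancestral
  state is undefined there.
- A gap or `X` never counts as "equal to *O*" (it breaks conservativeness
  when on the control side) and never supports *d*.
- The ≤1 non-supporting taxon per cluster may carry anything, including
  *O* or missing data: the condition constrains only six taxa.
- Columns conservative in both directions (all 16 ingroups = *O*) are
  counted toward neither category; no derived residue can exist there
  anyway under the per-cluster rule.
- If two distinct residues both meet the support threshold (impossible
  with 4-taxon clusters at threshold 3, possible in reduced designs), the
  column is rejected as ambiguous and logged rather than double-counted.
- Taxon names match case-sensitively across alignment, tree and design.
- Alignments are not trimmed by default; `drop_gapped_columns=True`
  restricts scanning to columns with no missing data in any design taxon
  (reported coordinates stay those of the input alignment, 1-based, so
  calls read like protein variants, e.g. `D401E`).

Foreground and background totals are compared with a two-cell Pearson
goodness-of-fit test against equal expectation, χ² = (f − b)²/(f + b) on
1 df — the comparison the mirrored design licenses. The statistic is
computed on raw substitution counts; per-gene deduplication (counting
genes rather than sites) is reported alongside but not tested. Note the
test is conservative when f + b is small (< ~20): the discrete support
cannot reach the 3.84 critical value until f + b ≥ 4, so at realistic
null rates (of order 10⁻⁴ per site) small datasets essentially never
reject. This is a property of the statistic, not an implementation
artifact, and is why calibration is reported as the empirical null of
counts rather than a p-value histogram.

## Substitution model

`models` implements the JTT empirical exchange matrix with arbitrary (or
the published default) equilibrium frequencies: Q_ij = s_ij π_j,
normalised so −Σ πᵢQᵢᵢ = 1, i.e. branch lengths are expected
substitutions per site. Rate heterogeneity across sites is discrete
gamma with shape α and k equal-probability categories (default k = 4),
using mean-of-category rates, which keeps the average rate exactly 1.
Transition matrices come from the eigendecomposition of the symmetrised
matrix diag(√π) Q diag(1/√π); entries are clipped to [0, 1] against
roundoff. Accuracy is ~10⁻¹² on unit branch lengths (verified by
Chapman–Kolmogorov and ergodic-limit tests).

## Likelihood and fitting

`phylo_lik` computes alignment likelihoods by Felsenstein pruning over
unique site patterns, with per-node rescaling for underflow and an equal
weight 1/k mixture over the gamma categories. Gaps and `X` are missing
data (flat partial likelihood). Equilibrium frequencies are the observed
residue proportions over the alignment ("+F"), floored at 10⁻⁶ so absent
residues keep the model reversible.

Fitting is coordinate ascent on a fixed topology: bounded Brent searches
over each branch length in [10⁻⁸, 20] and α in [0.02, 50], swept until
the log-likelihood gain per sweep falls below `tol` (default 10⁻⁶
log-units). Zero initial branch lengths are re-set to 0.05. The ascent
property (final ≥ initial likelihood) and re-rooting invariance of the
reversible model are tested; the engine was cross-checked against an
independent pruning implementation on a fixed fixture (frozen into the
test suite) and agrees to the fourth decimal.

Two caveats a user should know. First, the two branches adjacent to a
degree-2 root are individually non-identifiable under a reversible model
(only their sum is); parameter-recovery claims are therefore made on
trees with a basal multifurcation, where every branch is identifiable.
Second, per-gene fitting is the default; the pipeline fits one parameter
set on a concatenated sample capped at `max_fit_sites` columns (default
2000) because branch-length optimisation on large trees is the single
most expensive step and α stabilises quickly with concatenation.

## Simulation

`simulate` draws a root sequence i.i.d. from π, assigns each site one
gamma category uniformly (shared across the tree — standard
rates-across-sites semantics), and samples each child state from
P(t·rate) rows along a preorder traversal, recording every internal
node. A single seeded generator is consumed in a documented order (site
categories, root states, then one uniform vector per branch in
preorder), so datasets are bit-reproducible from the seed.

Recorded internal states support two calibrations:

- **Ancestral accuracy**: among sites conservative on the simulated
  leaves, the fraction where the simulated outgroup state equals the true
  simulated state at both cluster MRCAs on the opposite (non-conservative)
  side — exactly the nodes whose state the caller fixes to *O*. On the
  default tree this is ≈ 0.94, the quantitative support for the
  outgroup-as-ancestor assumption.
- **Null convergence**: per-replicate (foreground, background) call
  counts on no-signal simulations, used as the empirical null for
  observed counts.

## Synthetic studies

`synthetic_data.default_topology()` builds the 17-leaf study tree —
outgroup sister to two clades, each pairing a 4-taxon foreground cluster
with its 4-taxon background analogue — with every branch at a common
scale (default 0.1 substitutions/site, giving leaf-to-leaf paths up to
~1.0, commensurate with deep vertebrate divergences, and making the
foreground and background sides exact mirror images).
`generate_study()` evolves genes under JTT+Γ and overwrites
collision-free random columns with exact convergent patterns: controls
and outgroup at a residue *O* drawn from π, target taxa at *d ≠ O* drawn
from π excluding *O* (keeping planted columns compositionally similar to
neutral ones). `support="strict"` plants 8-of-8 carrier patterns (tests
recall in isolation); `support="minimal"` plants 3+3 patterns (tests
threshold sensitivity: recovered at the default threshold, rejected at
4). Defaults — 300-column genes, α = 0.8 — are typical of vertebrate
protein alignments.

What the generator does *not* emulate: alignment error, indels,
compositional drift across lineages, among-branch rate variation, or
ortholog mis-assignment. Passing tests therefore demonstrate correctness
of the caller and calibration machinery under the model, not robustness
of the biological conclusions to real-data artifacts.

## Rate analyses

- **Tajima relative rate test**: counts of lineage-unique differences
  m₁, m₂ against an outgroup, referred to χ²₁ via (m₁ − m₂)²/(m₁ + m₂)
  (the usual approximation); an exact two-sided binomial is available via
  `exact=True`. Sites with any missing symbol are excluded.
- **Fourfold-degenerate extraction**: a codon column is retained iff all
  taxa have unambiguous codons sharing one two-nucleotide prefix that
  heads a 4D family of the standard genetic code (TC, CT, CC, CG, AC,
  GT, GC, GG). This strictest reading guarantees third-position
  neutrality in every lineage; a per-reference-taxon relaxed mode is
  available. Alternative genetic codes are out of scope.
- **K2P distance**: d = −½ ln((1 − 2P − Q)√(1 − 2Q)) with pairwise
  deletion of non-ACGT sites; saturated pairs return ∞ with a warning.
  These closed-form distances serve as the neutral-distance step in place
  of full GTR+Γ branch-length re-optimisation, which is outside this
  package's scope.

## Pipeline and reproducibility

`pipeline.run_pipeline` chains synth/load → fit → scan → null →
report, writing per-site and summary TSVs plus a run log; the master
seed is split into per-stage seeds with `numpy.random.SeedSequence`, the
header of every output records seed and flags, and reruns are
byte-identical. Stage failures rename partial outputs with a `.partial`
suffix. Problem sizes used by the validation scripts — 400 × 2000-site
null replicates, 50,000-site parameter recovery, 20,000-site accuracy
estimates — were chosen so each quantity's Monte-Carlo error is well
below the tolerance being checked while the whole battery runs in about
a minute.

## Known limitations

- The caller detects identical parallel substitutions only; convergent
  but non-identical replacements and probabilistic ancestral
  reconstruction are out of scope.
- The two-cell χ² is conservative at small counts (see above).
- Empirical frequencies are global, not per-gene-category; codon models
  and dN/dS are not implemented.
- The simulator has no indels; gaps only enter via real or synthetic
  input alignments.
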