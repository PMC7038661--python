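# Methods

## Scope and data model

The package reconstructs, on synthetic data with known ground truth, the
computational chain used to characterize constitutive OxyR activation:
expression decomposition into independently modulated gene groups
(i-modulons), structural proximity of mutations to OxyR stability features,
screening of allele collections for constitutive-activation substitutions,
a proteome-allocation growth-cost model, and lag-phase dose-response
estimation. Expression lives in an `ExpressionMatrix` (genes × samples,
log scale, condition/replicate labels, one designated reference condition);
structures in residue-indexed heavy-atom coordinate maps; alleles as
genome-id → CDS collections; growth data as tidy (time, OD, dose, strain,
replicate) tables.

## Robust ICA of expression

The matrix is first centered per gene to the mean of the reference
(wild-type) condition, so component activities read as deviations from the
baseline state — wild-type activity bars sit at zero by construction.

FastICA (scikit-learn, logcosh contrast, unit-variance whitening) is run
from `n_restarts` random initializations. Component gene-weight vectors
from all restarts are clustered by average-linkage agglomeration on
`1 − |Pearson r|` distance with a cut at 0.2; clusters recurring in at
least `min_recurrence` (default 0.5) of restarts survive. These
conventions — clustering threshold, recurrence fraction, restart count —
follow common robust-ICA practice; the decomposition is reproducible given
the seed.

Each surviving cluster's centroid (sign-aligned mean of its members) is
refined in one alternating step: activities are estimated by least squares
from the centroids on the column-centered matrix, then weight vectors are
re-estimated by regressing the reference-centered matrix on those
activities. This step matters because FastICA sources are gene-centered;
without it the span of `S` misses the per-sample mean component and
`S·A` cannot reconstruct the centered matrix to near the rank-k optimum.
Final conventions: unit L2 norm per component, sign fixed so the
largest-magnitude weight is positive, activities as the least-squares
projection of the centered matrix onto `S`.

Numerical guard: on noise-free inputs, reference-condition columns are
exactly zero, and scikit-learn's deterministic sign convention
(`u *= sign(u[0])`) zeroes a whitening component whenever the first
sample's loading is exactly zero. A seeded jitter of relative magnitude
1e-9 breaks these exact ties without measurably changing the decomposition.

**Membership** uses a robust cutoff: genes whose weight deviates from the
median weight by more than `k` (default 5) robust standard deviations
(MAD × 1.4826). On noiseless data the MAD collapses to zero while a few
percent of cross-component leakage survives, so the threshold is floored at
10% of the maximum deviation; this assumes true member weights lie within
10× of the component's top weight, which holds for the generator's weight
profiles and for typical regulons. **Regulator linkage** is the
hypergeometric tail probability of the member/regulon overlap,
Bonferroni-corrected over the regulons tested. **Differential activity** is
Welch's two-sample t on replicate activities; with two identical groups the
test reports difference 0, p = 1.

### Known limitation: cross-component leakage under extreme activations

Whitening-based ICA carries a small deterministic separation bias (~1–2% of
weight mass for the default planted geometry). When one component's
activity swing is enormous relative to replicate noise — exactly the regime
of constitutive OxyR activation — that leakage induces a systematic offset
of order (leakage × swing) in other components' activities, which a t-test
with near-zero replicate variance will flag as significant. A null
component's *p-value* is therefore not a calibrated negative control
downstream of ICA at extreme effect sizes; the meaningful negative control
is the *magnitude* of its activity change relative to the driven component
(~2% under the default conditions). The differential test itself is
calibrated (nominal type-I error) when activities carry no planted
difference, which the test suite verifies directly.

## Structure proximity

Distances are minimum Euclidean heavy-atom distances between residue pairs
(hydrogens dropped, highest-occupancy altloc retained, first chain by
default). A CA-only metric is available (`metric="ca"`); the minimum
heavy-atom form is the stricter notion of proximity and is the default.
Residues unresolved in a conformer yield flagged missing cells — never an
imputed number.

Classification of a mutation's predicted conformational bias is a pure
function of (distance row, region annotation, contact cutoff). Precedence:

1. redox loop [199, 208] → `destabilizes_reduced` (the loop is required for
   tetramerization of the reduced form);
2. flexible loop [205, 216] → `redox_loop_flexibility` (the loop governs
   Cys-199's return to the inward, reduced conformation);
3. proline arrangement {99, 103, 107, 111} → `proline_interface`;
4. otherwise the category of the nearest feature within the contact cutoff
   (default 8 Å, configurable; reported distances are raw, the cutoff only
   gates the fallback label);
5. otherwise `ambiguous`.

The redox loop is checked before the broader flexible loop because it is
the more specific annotation: Cys-208 lies in both, and its documented
phenotype (loss of reduced-tetramer stability) belongs to the redox-loop
mechanism. Cross-chain (dimer-interface) distances are out of scope.

## Allele screening

CDS collections are deduplicated by exact string identity at the DNA level
and, after translation (bacterial code, table 11; terminal stop trimmed),
at the protein level. Records with ambiguity codes or frame problems are
flagged and excluded from calling; internal stops are flagged as pseudogenes
and excluded from protein grouping only.

Substitutions are called from a global protein alignment (BLOSUM62,
gap open 11 / extend 1 — conventional protein-alignment penalties).
Identity is identical aligned pairs over alignment length; similarity is
positive-substitution-score pairs over alignment length. Alignments under
50% identity (configurable) are rejected as a different gene. Indels are
reported separately and never matched against the constitutive set.

Screening supports two rules. `position_match` (default) flags any
nonsynonymous change at a reference-set position; `exact_match` also
requires the variant residue. Position matching is the default because
natural-isolate changes recur at the evolution-identified positions with
*different* variant residues (A213T beside A213P/E, A147V beside A147E,
L200V beside L200I, P107T beside P107L), so exact matching would miss the
phenomenon being screened for. Cross-species positions are mapped through
the same global alignment, with gap columns returned as unaligned.

The reference OxyR sequence bundled with the generators is a synthetic
stand-in: a random 305-residue protein with the functionally annotated
residues pinned at their true E. coli positions. Every positional analysis
is exercised on the real coordinate system, but no sequence-identity
claims are made from the stand-in.

## Proteome cost

The full metabolism-and-expression simulation is replaced by the minimal
linear allocation model consistent with its two observed scaling laws:
relative growth `μ/μ₀ = 1 − α·φᵢ·(fᵢ − 1)/Φ` for a single gene (affine in
the fold change fᵢ), and slope `kᵢ = α·φᵢ/Φ` increasing with the gene's
reference abundance φᵢ. α is shared across genes — slope variation is
attributed to abundance alone. Multi-gene costs add; the rate is floored at
0 and capped at 1 (no reallocation gains below reference expression, by
default). Fold changes are interpreted against the growth-optimized
reference expression state. `fit_cost_model` recovers α/Φ by least squares
on (1 − μ/μ₀) against φᵢ(fᵢ − 1), excluding points at the zero floor (the
floor is a model cap, not data), and raises a misfit flag when per-gene
slopes imply coefficients differing by more than 5% relative — e.g. genes
of equal abundance with different fitted slopes.

## Lag-phase estimation

The default tangent method works on log OD: baseline is the median of the
first 3 points; the steepest 5-point sliding-window regression line on
log OD (windows still at baseline are excluded) is extended back to the
baseline log-OD level and the crossing time is the lag. The estimator is
exactly equivariant under time translation and invariant under
multiplicative OD rescaling. A threshold method (first time OD exceeds
baseline + Δ, default 0.02) is provided for robustness checks. Curves whose
rise above baseline stays below Δ_min (default 0.05 OD) are "no growth":
the lag is undefined and downstream summaries carry a flag, never a number.
Relative lag increase is (lag_treated − lag_control)/lag_control against
the same strain's zero-dose control; replicates are estimated individually
and then summarized, never pooled into one fit.

With the generator's lagged-logistic curves (growth at μ_max = 0.9/h from
an OD-0.05 baseline toward capacity 1.0, sampled every 0.25 h, OD noise
0.005), the median absolute lag error over 100 seeded curves is ~0.08 h,
well under one sampling interval; the residual positive bias comes from the
logistic's curvature within the tangent window.

## Synthetic generators: what they emulate and what they do not

* **Expression**: `X = S·A + ε` with i.i.d. Gaussian noise on the log scale
  (σ = 0.25 by default, a typical replicate spread for log-TPM data) —
  planted sparse, signed, roughly zero-mean weight profiles over a
  1,000-gene universe, two 20-gene modulons ("OxyR" strongly activated in
  evolved conditions, difference 8 activity units; "SoxS" varying only in a
  non-contrast condition as negative control), 4 conditions × 3 replicates.
  Signed weights reflect real ICA components (both up- and down-responding
  genes); for a strictly same-signed regulon, planted sources become weakly
  correlated and the leakage discussed above grows. Not emulated: count
  noise, batch effects, library-size artifacts.
* **Alleles**: planted nonsynonymous changes with controlled synonymous
  extras and duplicate structure under codon table 11. No codon-usage
  realism or read-level errors.
* **Structures**: jittered extended chains with 1–3 heavy atoms per residue
  and rigid per-residue displacements between conformers, so every distance
  has a closed form. No stereochemistry or physics.
* **Growth**: lagged logistic with dose-dependent lag and optional
  no-growth doses. The baseline is the inoculum OD (plate blank assumed
  pre-subtracted); no death phase, no mechanistic peroxide decay.

Passing recovery tests on these generators demonstrates the inference
chain's correctness under its stated assumptions, not robustness to the
artifacts real data add on top.

## Determinism and degenerate inputs

All generators and the decomposition are reproducible bit-for-bit given a
seed; the pipeline manifest records parameter values and sha256 hashes of
every output, and two runs with the same config hash identically. All-zero
expression matrices return zero components with a degenerate flag;
constant weight vectors, empty condition lists, non-monotone time axes,
negative fold changes and empty reference sets are rejected with named
errors; fewer robust components than requested is a flagged result, not an
error.
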