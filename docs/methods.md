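# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Data model and preprocessing

All quantitative layers are features × samples matrices over one sample
design (default: 3 normal cortex, 4 PDGFRA, 3 NTRK, mirroring a 10-plex
TMT experiment). Matrices ingest as raw nonnegative intensities (or
FPKM); rows with any missing value are dropped and counted, matching the
"quantified in every sample" convention. All statistics run on the log2
scale. Zeros are floored at half the smallest positive value of the
layer before logging. TMT columns are median-centered per sample on the
log2 scale (scale normalization); isobaric ratio compression mostly
rescales fold changes and has little effect on differential calls after
this normalization, so no compression correction is attempted.
Phosphosites are identified by the composite string
`PROTEIN_<residue><position>` (e.g. `BRCA1_S686`).

## Differential expression

One-way ANOVA F per feature; significance by permuting the group-label
vector identically across features. The permutation p uses the
+1-smoothed estimator `(1 + #{F_perm ≥ F_obs})/(B + 1)` (never exactly
zero); B = 1000 by default. An `exhaustive=True` mode enumerates all
distinct label assignments for small designs and then reports the exact
enumeration fraction without smoothing. Features with zero variance
everywhere are flagged with p = 1. BH step-up q-values are primary; a
Storey variant rescales them by π₀ estimated from the p-density above
λ = 0.5. DE requires p ≤ 0.05 and a largest pairwise group-mean
difference of at least log2(1.5) (proteome/transcriptome) or log2(2.0)
(phosphosites); ties at the cutoff are included. Fold changes are
computed post-normalization.

The final FDR of a DE set is estimated by re-permuting labels and
counting features that pass both cutoffs under the permutation, where a
permuted feature's p is its rank within the feature's own permutation
pool. A structural property of this estimator: a feature passes the rank
cutoff in exactly ~p_cut of permutations regardless of signal strength,
and permutations extreme enough to pass the rank test also concentrate
enough signal to pass the fold filter, so on data with strong planted
effects the estimate sits at ≈ p_cut (0.05) rather than below it; on
pure-noise data it is ≈ 1. The tests assert exactly this behavior.

## Phosphosite localization

The protein-level Lscore of a site is the maximum PSM Lscore over its
supporting PSMs. A PSM is ambiguous when its top two candidate Lscores
differ by < 10 percentage points (the Lscore is itself a 0–100 scale, so
the gap is read as absolute points). Resolution order: (i) clear winner;
(ii) strongest protein-level evidence, pooled from well-localized PSMs;
(iii) heuristic residue order SP-motif > S > T > Y, with the SP motif
checked on the identified peptide (candidate residue immediately
followed by P); remaining ties rank candidates by the best supporting
Jscore and finally by residue position (logged). Resolution is
deterministic and invariant to candidate input order.

## Coexpression clustering

Similarity is `max(Pearson r, 0)` over all samples — negative
correlations are clipped, so anti-correlated features are maximally
distant; constant features are excluded. The tree is average linkage
(config-exposed). The published workflow uses a hybrid dynamic tree cut;
this package re-implements the described behavior as a fixed-height cut
(default 0.5 on the 1 − max(r,0) distance) followed by minimum-size
pruning (default 30 members, the usual WGCNA convention) and iterative
merging of clusters whose eigengene correlation distance falls below
0.15. The eigengene is the first right-singular vector of the
feature-standardized member matrix, unit norm, sign-oriented so the mean
member correlation is positive. All DE features are then (re)assigned to
the cluster with the highest positive eigengene correlation; features
below r = 0.3 stay unassigned, and exact ties break toward the smaller
cluster id (logged). Proteome and phosphoproteome are clustered
separately.

## Enrichment and kappa modules

Cluster-to-pathway enrichment is the right-tail hypergeometric
probability (identical to a one-sided Fisher exact test on the 2×2
table; the tests assert that identity), BH-corrected across sets at
q ≤ 0.05. Enriched pathways are linked when the Cohen's kappa of their
gene-membership indicators reaches 0.5; the membership universe is the
union of the enriched pathways' genes (the ClueGO convention). Network
modules are connected components, numbered by decreasing size then
lexicographic order, independent of input order. Note that kappa over a
two-pathway universe is degenerate (no "neither" cell), so meaningful
linking requires pooling pathways across clusters or terms.

## Kinase activity

Sites are first normalized for substrate abundance: per sample,
log2(site) − log2(parent protein); orphan sites pass through flagged.
The model is additive on log2 scale: a normalized site value is the sum
of the activities of its annotated kinases in that sample. Activities
are estimated by full-batch gradient descent on the ridge-penalized
squared error (λ = 1e−6 for identifiability; step size 1/L from the
design-matrix Lipschitz constant; up to 400 iterations, relative
objective tolerance 1e−8) from 10 random N(0,1) initializations. The
reported activity is the restart mean; the restart SD is the convergence
diagnostic — the problem is convex, so well-identified kinases converge
to the same optimum from every start, while flat (non-identifiable)
directions leave restart scatter that the 0.2-SD filter catches.
Acceptance additionally requires ≥ 3 observed substrates — or rescue by
an upstream kinase (an accepted kinase with a substrate site on this
kinase) sharing the same coactivation ordering — and BH q ≤ 0.05 from a
per-kinase ANOVA of activity across groups. Shared substrates are
handled by the joint fit rather than by splitting signal. Superfamily
summaries test each family's activation count against the rest by
one-sided Fisher exact (significance cutoff 0.001) and compare group
pairs by chi-square on which group each kinase is more active in.

## TF activity

Per layer, a one-sided Fisher exact test of regulon overlap with the DE
set over the layer's universe (transcriptome universe: expressed genes;
proteome: quantified proteins), BH across TFs, q ≤ 0.05. A TF is
accepted only when significant in the transcriptome AND in at least one
proteome coexpression cluster AND its protein was itself detected by MS.
"Significant in both layers" is read as significance per layer, not
same-cluster co-membership. Accepted TFs are validated by their own
protein-level DE and/or an annotated activation phosphosite that is DE
with a positive tumor change; activation-site annotations are an input
table. Activator/repressor mode is a one-sided sign test (p < 0.05) on
the tumor-vs-cortex fold changes of the TF's targets; fewer than five
informative targets, or no significant direction in either tail, yields
"undetermined" — a three-way outcome is preferred over defaulting to
activator, so an evenly split regulon is never force-classified.

## Coactivation networks

A coactivation pattern is the ordering of group means of a per-sample
profile, with the minimal adjacent gap recorded as its margin; gaps at
or below `margin_min` (default 0, i.e. exact ties) flag the pattern
ambiguous. Edges are accepted only on identical strict orderings:
kinase→kinase direct edges need a substrate-site relation plus matching
patterns; indirect edges connect two kinases through exactly one
accepted intermediate (path length 2). Kinase→TF edges require agreement
of (a) kinase activity, (b) the phosphorylation of the kinase's site on
the TF, and (c) the mean transcript profile of the TF's targets. This
formalizes a curation rule that was originally manual; the margin makes
its stringency explicit and monotone (raising it never adds edges).

## Pathway activity a(P)

a(P) = Σᵢ Cᵢ·Fᵢ/√k over the k pathway proteins with annotated
functional phosphosites. Fᵢ is the arithmetic mean of the log2 fold
changes (tumor group mean − cortex mean) of the protein's DE annotated
sites. Cᵢ is +1 for tumor-promoting, −1 for tumor-inhibiting
phosphorylation; sites with conflicting annotations are excluded, and a
protein whose sites disagree in sign is excluded as conflicted (a
conservative extension of the site-level rule). k counts proteins, not
sites. The bootstrap null draws k values with replacement from the fold
changes of all quantified phospho events, applies the C template, and
uses the strict-inequality convention p = #{a(P)_sim > a(P)_obs}/10,000.
Under the null the p-value is uniform to within the 1/n_boot grid; the
acceptance suite verifies type-I error at α = 0.05 within [0.04, 0.06]
over 5000 trials. The group-activity ratio is reported with both
groups' bootstrap p-values; a non-positive denominator falls back to the
difference. Pathway analysis deliberately uses un-normalized phospho
data — protein abundance is part of pathway engagement — while kinase
inference uses normalized data.

## Cross-species convergence

Mouse and human expression are matched by quantile normalization over
1:1 orthologs (rank-mapped to the pooled mean order statistics, average
ranks for ties; idempotent). Mouse candidates need strict
NTRK > PDGFRA > cortex transcript ordering, ≥ 2-fold NTRK over PDGFRA,
Student's t p ≤ 0.05, and a same-direction proteome or phosphoproteome
change (nominal p ≤ 0.05 when test tables are supplied — the
"consistent change" requirement is not quantified in the source
workflow, so same-sign-with-nominal-significance is the default).
Human candidates are genes with higher transcript levels in NTRK-fusion
than PDGFRA-mutant cases (one-sided pooled t, p ≤ 0.05; FPKM > 1 floor;
a rank fallback when a class has fewer than two cases). Convergent
candidates are the orthology intersection.

## CRISPR dropout analysis

Counts are scaled to CPM per replicate and log2-transformed with
pseudocount 1 (depth-invariant). The replicate unit is the per-replicate
log2(final/start) ratio of each construct. Each construct is tested
one-sided (dropout) against the pooled nontargeting ratios by Student's
t; `significant_down` requires p ≤ 0.05 and a mean below the control
mean — enrichment is reported but never a hit. A gene is essential when
≥ 2 of its 3 constructs drop out (genes with n ≠ 3 constructs use
⌈2n/3⌉ and are flagged); the nontargeting pseudo-gene is never
eligible. The threshold for "significantly decreased" is config-exposed
(default 0.05).

## Depth QC

Fully tryptic digestion cleaves after K/R except before P, up to two
missed cleavages; concatenating the zero-missed peptides reconstructs
the protein. Monoisotopic masses come from the standard residue table
(no variable modifications); hydrophobicity is the mean Kyte–Doolittle
index, as the original hydrophobicity model is unspecified. Observable
peptides need length ≥ 7, mass within (700, 5000) Da and hydropathy
within (−2, 2) by default (both windows config-exposed; in a real
analysis they would be derived from the identified-peptide
distribution), and an expressed parent transcript (FPKM > 1). Coverage
is residue-based against the observable space; proteins without
observable peptides are excluded from the mean rather than counted as
zero.

## Synthetic data: what it emulates and what it does not

Noise is lognormal on intensities (Gaussian on log2, default SD 0.25 per
cell), the standard working model for TMT reporter data. Group effects
are built from five directions evenly spaced in the replicate-weighted
2-D space of centered group contrasts, scaled to unit per-sample SD;
direction 0 is the monotone cortex < PDGFRA < NTRK axis that dominates
the tumor biology, and centering keeps per-sample medians stable so
median centering does not erode planted effects. Defaults: 2000
proteins (+ 20 TF and 30 kinase proteins), 5000 phosphosites, 3000
transcripts; five planted clusters of 60 features per layer with effect
size 1.0; 30 kinases (24 active, effect 1.0, per-sample jitter 0.15,
3–8 substrates each, two 2-substrate kinases rescued by upstream
partners); 20 TFs (8 active, 30 targets each, effect 0.5 — kept below
the 2-fold cross-species stringency so regulon targets do not leak into
the convergence filter); 22 pathway proteins with one functional site
each (17 promoting, 5 inhibiting), PDGFRA-vs-cortex shifts drawn from
±U(1.2, 2.5) and NTRK shifts exactly 1.45× those, so the planted
activity ratio is 1.45 by construction; 20 convergent genes (transcript
levels 0/1.0/2.6, protein 0/0.8/2.0 — strong enough that the df-5
consistency t-test rarely misses); a 3 NTRK-fusion vs 8 PDGFRA-mutant
human cohort (shift 1.8, SD 0.6); a screen of 9 master regulators (5
essential) plus 6 cross-species genes (1 essential), negative-binomial
counts with mean 500, dispersion 0.05, 8-fold dropout, triplicate, 6
nontargeting controls.

Not emulated: spectra, retention times, TMT ratio-compression physics,
missingness structure (matrices are complete), batch effects,
inter-patient heterogeneity in the human cohort, and curation noise in
the relationship tables. Passing tests therefore demonstrate the
correctness and calibration of the inference machinery under the stated
generative model, not robustness to those real-data pathologies.

## Problem sizes used in tests and the acceptance script

Multi-seed checks run 20 seeds at the default study size with 300
permutations for DE (granularity 1/301 is ample for a 0.05 cutoff);
bootstrap checks use the full 10,000 replicates; the CRISPR rule check
runs 200 screens; the acceptance script averages the pathway ratio over
5 seeds and the screen over 100 seeds. These sizes were chosen so each
quantity's Monte-Carlo error is small against its acceptance band.

## Known limitations

- The kinase-activity objective is the simplest model satisfying the
  stated contract (additive least squares with ridge, restarts,
  convergence filter); the original inference tool's exact objective is
  not public in the source description, so coefficients are comparable
  in pattern but not numerically to that tool.
- The permutation-FDR estimator's concentration at the p-cutoff for
  strong signals (see above) means its value is informative mainly on
  near-null data.
- Kappa modules depend on the pooled universe; with very few enriched
  pathways kappa is close to degenerate.
- The dynamic-tree-cut re-implementation uses a fixed-height cut; on
  data with nested cluster structure at very different scales it can
  split or merge differently than the original hybrid algorithm.
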