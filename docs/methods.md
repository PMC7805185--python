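# Methods

This note documents the models, conventions and numerical choices behind
`semipep`, and what the synthetic-data generator does and does not
emulate.

## Tryptic status and cleavage-site nomenclature

A peptide terminus counts as tryptic when the preceding residue is K or R
(N-terminus), the last residue is K or R (C-terminus), or the terminus
coincides with a protein terminus. The protein N-terminal exception covers
start positions 1 **and** 2, because initiator methionine is commonly
removed co-translationally; this is configurable back to position 1 only
(`classify_peptide(..., nterm_positions=(1,))`). Trypsin specificity is
K/R at P1 with no proline restriction; a strict "not before P" variant is
exposed via the digestion utilities for users who need it.

Cleavage sites are described in Schechter–Berger notation, P6-P5-P4-P3-P2-
P1 ↓ P1′-P2′-P3′-P4′-P5′-P6′, with the scissile bond between P1 and P1′.
For a SEMI_N peptide the P6–P1 positions come from the last six characters
of the N-terminal cleavage window and P1′–P6′ from the first six residues
of the peptide (continued into the C-terminal window when the peptide is
shorter than six residues); SEMI_C is the mirror image. Positions beyond a
protein terminus carry the pad character `_` and are excluded from both
the numerator and the denominator of motif frequencies at that position —
a truncated site is not dropped wholesale.

Cleavage windows have a configurable fixed width, default 15 residues
(the MaxQuant cleavage-window convention). Positions are 1-based
inclusive in the leading (first-listed) protein, which also supplies the
flanking context; all accessions are kept for source classification.
Blank or zero LFQ cells are missing values, never measured zeros.

## In-source fragment discrimination

Semi-tryptic species can be artifacts of in-source fragmentation. Such
fragments co-elute with their fully tryptic parent and carry a lower
charge, because the parent's charge is divided between fragments. A
peptide is flagged in a sample only when **all** of the following hold
for some candidate parent detected in the same sample: (i) the parent is
a fully tryptic superstring at the same locus sharing the fragment's
tryptic terminus; (ii) |ΔRT| ≤ `rt_tol_min` (default 1.0 min); (iii) the
fragment's charge is strictly lower; (iv) the fragment's standardized
residual under the retention-time model exceeds `resid_z` (default 3.0)
while the parent's does not. The joint AND is deliberately conservative:
false exclusion of genuine proteolysis products is the costlier error.
Flagging is monotone in the RT tolerance.

The RT model is a per-sample calibrated additive model, RT ≈ intercept +
Σ residue-count·coefficient + c·ln(length), fitted by centered least
squares on the fully tryptic peptides of that sample. Centering makes the
degenerate constant-RT case exact (zero coefficients, intercept = mean)
and improves conditioning. A fit on fewer than 50 peptides (or a
rank-deficient design) is flagged unreliable, and criterion (iv) is then
skipped with a warning. An external hydrophobicity predictor is not
needed because only a relative deviation criterion enters the rule.

## Closest-fully-tryptic conversion and annotation

Peptide→taxon indices are built from tryptic digests, so semi-tryptic
peptides are converted before lookup: SEMI_N prepends residues from the
N-term window up to (excluding) the nearest K/R; SEMI_C appends from the
C-term window up to (including) the nearest K/R; a pad is a protein
terminus and therefore a valid boundary. If no boundary lies within the
window the peptide is returned unchanged and flagged unresolved; such
peptides keep their functional annotation (keyed on the leading protein
accession) but receive no taxonomic assignment.

LCA assignment intersects root-to-node ancestor paths over a local
NCBI-style tree and returns the deepest shared node, with lineages
reported at the seven canonical ranks (gaps allowed). I and L are equated
by default — they are isobaric and indistinguishable by MS. An opt-in
missed-cleavage mode splits peptides with internal K/R into constituent
tryptic units and takes the LCA of the intersected taxon sets; it is
opt-in because its benefit depends on the completeness of the peptide
index. EC numbers are truncated to sub-class (two fields, e.g. `1.15`)
for grouping.

Group membership is sample-independent and closed over lineages: a
peptide with a genus-level LCA belongs to the genus and every ancestor
group. A peptide with several GO terms or EC sub-classes contributes its
full intensity to each — a documented double-counting property across
overlapping functional groups, standard in peptide-centric annotation.

## NRASP

Relative abundance of group *g* in sample *s* within stratum
(semi or full) is the summed LFQ intensity of the group's stratum
peptides divided by the summed intensity of **all** stratum peptides in
the microbial partition of that sample (global-per-stratum
normalization; a per-taxon-restricted alternative is a matter of passing
a different record subset). NRASP(g, s) = semi(g, s) / full(g, s), with
missing (never imputed, never infinite) cells wherever the fully tryptic
denominator is zero or unquantified. The index is invariant to per-sample
intensity rescaling, and a group whose semi- and fully tryptic signals
change proportionally keeps NRASP constant — the rationale for
normalizing at all. Imputation happens only inside PLS-DA, via BPCA.
In-source-flagged (peptide, sample) pairs are excluded before any
abundance is computed. Presence filtering keeps features quantified in at
least ⌈0.75·n⌉ samples by default.

## Statistics

- **Kruskal–Wallis + Dunn–Bonferroni.** KW uses the tie-corrected H;
  Dunn's pairwise z uses the pooled-rank variance with tie correction,
  n(n+1)/12 − Σ(t³−t)/[12(n−1)], and Bonferroni multiplies by the
  k(k−1)/2 group pairs **per feature**. Correction across features is a
  separate, opt-in BH-FDR step. Missing values are dropped per feature; a
  feature with fewer than two groups of ≥ 2 observations is skipped with
  a note.
- **Bray–Curtis / PCoA.** D(i,j) = Σ|x_i−x_j| / Σ(x_i+x_j) with missing
  abundances treated as zero; a pair of all-zero samples gets distance 0
  with a warning. PCoA double-centers (Gower), eigendecomposes, scales
  eigenvectors by √λ, excludes negative-eigenvalue axes (magnitudes
  recorded; Cailliez-type correction intentionally not applied by
  default) and reports explained variance relative to the positive
  eigenvalue sum. Jaccard dissimilarity on presence/absence is available
  as an alternative metric.
- **BPCA imputation.** Probabilistic PCA fitted by EM with the missing
  cells as latent variables: each iteration re-estimates the principal
  subspace from the completed matrix (W = V·√max(λ−σ², 0), σ² = mean
  trailing eigenvalue) and replaces missing cells by their conditional
  expectation given the observed cells of the same sample. The
  √(λ−σ²) weighting shrinks directions at or below the noise floor to
  exactly zero, which plays the role of automatic component-relevance
  shrinkage; a full ARD prior was judged unnecessary for this use.
  Defaults: q = min(n−1, 10, d) components, tol 1e-6, max_iter 500.
  Observed entries are returned unchanged; a feature with a single
  observed value falls back to that value with a warning.
- **PCA / PLS-DA.** PCA by SVD of the centered (optionally scaled)
  matrix. PLS-DA extracts NIPALS latent variables against one-hot group
  indicators; score vectors are mutually orthogonal. The requested number
  of latent variables is truncated to the effective rank (singular values
  above max(1e-8·σ₁, 1e-9)); a matrix without variation is rejected, and
  the pipeline records PLS-DA as absent rather than failing the run.
- **Cross-block correlation.** Spearman R over all pairs of the top three
  axes of two sample-score blocks, aligned on shared sample ids (≥ 3
  required); a pair is *reported* when |R| > 0.2 and p < 0.05.
- **Clustering.** Agglomerative (average linkage, Euclidean by default)
  clustering of significant features' group means, returning merge
  heights and leaf order for heatmap display.

## The synthetic metaproteome generator

The generator emulates the statistical structure the analysis assumes,
with ground truth for every emitted peptide (true status, cleavage
window, parent, in-source flag).

- **Proteome and annotations.** Random proteins (default 200 microbial,
  plus small human/food/contaminant partitions) with UniProt-like residue
  composition, assigned to the species of a fixed toy gut taxonomy
  (2 phyla → 4 genera → 8 species) and to GO-BP/EC labels. The
  peptide→taxa table is built by in-silico tryptic digestion of the
  microbial partition.
- **Digestion.** Cleavage after K/R, up to 3 missed cleavages, length
  7–30, with a detection subsample (default 35 % of candidates).
- **Intensities.** Hierarchical: protein abundances are log2-normal
  (μ = 20, σ = 2) and peptides inherit them through a 0.5-log2 response
  factor, so the marginal peptide distribution is log-normal with
  σ ≈ 2.06. Per-sample variation adds 0.3 log2 units.
- **Endogenous proteolysis.** Each protein diverts a fixed fraction
  (default 0.25) of its detected tryptic signal into Poisson(8) cleavage
  products, split evenly across realized products with 0.25-log2 yield
  noise. Event positions fall on abundant parent peptides proportionally,
  and the P1 residue is drawn with configurable preference weights.
  Per-group, per-taxon rate multipliers modulate the diverted signal, so
  a multiplier of 2 doubles a taxon's semi-tryptic signal in that group.
  This "fractional diversion" construction makes uniform proteolysis
  yield group NRASP ≈ 1 by design — the null the index is meant to
  recover — and gives ≈ 23 % semi-tryptic identifications under the
  defaults, inside the 12–26 % range observed in real gut metaproteomes.
- **Detection.** One shared detection draw per peptide, logistic in log2
  intensity (midpoint μ − 1.5σ, width 0.7): abundant peptides are almost
  always identified, faint ones drop out, as in real LC-MS data. All
  engines see the same underlying signal; independent per-engine dropout
  and an intensity-dependent high-PEP probability model the residual
  engine disagreement. A uniform-detection mode
  (`intensity_detection=False`) exists for tests that need exhaustive
  emission.
- **Retention time and in-source fragments.** RT follows a fixed additive
  residue-coefficient table plus 0.3 min noise. In-source fragments are
  truncations (≥ 40 % of residues removed) of fully tryptic parents with
  charge reduced by one and RT within ± 0.2 min of the parent — thereby
  satisfying the discrimination criteria by construction, while genuine
  proteolysis products keep composition-consistent RTs.

**What passing tests do and do not show.** The generator reproduces the
marginal and group-level structure the pipeline's statistics assume:
log-normal intensities, intensity-dependent missingness, multi-engine
consensus, proportional semi/full coupling under the null. It does not
model chromatographic drift, post-translational modifications, shared
peptides between homologous proteins of different taxa (random sequences
make cross-taxon collisions vanishingly rare, so LCA specificity is
optimistic), protein inference ambiguity, or spectrum-level errors.
Passing the recovery tests shows the pipeline detects the modeled signal
classes at desk scale (200 proteins, 3 groups × 10 samples, sizes chosen
so the full suite runs in minutes); it does not certify sensitivity on
real cohorts.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `pep_threshold` | 0.05 | keep identifications with PEP strictly below |
| `presence` | 0.75 | minimum fraction of samples quantified per feature |
| `alpha` | 0.05 | significance threshold on adjusted p |
| `report_min_abs_r` | 0.2 | PCo correlation reporting rule |
| `rt_tol_min` | 1.0 min | in-source co-elution tolerance |
| `resid_z` | 3.0 | in-source RT-residual threshold |
| `window_len` | 15 | cleavage-window width |
| `equate_il` | true | I/L equated in taxonomy lookup |
| `match_on` | sequence | cross-engine matching key (strict; I/L-equated optional) |

Cross-engine intersection matches on the plain sequence by default
because I/L equating belongs to the annotation stage; quantities come
from the designated quantitation engine (MaxQuant LFQ by convention).
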