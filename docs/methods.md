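# Methods

## The enrichment model

The pipeline treats a metabolomics dataset as a samples × metabolites
intensity matrix with no knowledge of its experimental design. The working
assumption is that systematic between-group differences dominate the top
principal components of the log-intensity matrix, so PC loadings can stand
in for a differential-abundance statistic. Concretely, for each dataset:

1. **Zero replacement.** Zeros (non-detects) are replaced by one tenth of
   the dataset's global minimum non-zero intensity — one value per dataset,
   so within-column rank order is preserved — and the matrix is
   log2-transformed. An all-zero matrix has no valid replacement and is an
   error. The log base is irrelevant to everything downstream (it rescales
   all loadings by a constant), and base 2 is fixed for bit-reproducibility.
2. **PCA.** Samples are observations, metabolites features; features are
   mean-centered but not variance-scaled (the log transform already
   compresses scale, and scaling would re-weight quiet metabolites upward).
   The minimal prefix of PCs whose cumulative explained-variance fraction
   reaches 0.75 is retained. Loadings are unit-norm principal-axis
   components; GSEA depends only on their ranking, which any positive
   rescaling preserves, so the unit-norm convention is observationally
   neutral.
3. **Preranked GSEA.** For each selected PC, metabolites are ranked by
   loading (descending, ties broken by ascending metabolite index for
   determinism). For a pathway with k of N metabolites, the running sum
   increments at each member by |score|^q normalized over members (weight
   exponent q = 1 by default) and decrements by 1/(N−k) at each
   non-member; the enrichment score ES is the extreme of maximal absolute
   value, so |ES| ≤ 1. When the maximal positive and negative deviations
   tie exactly in magnitude — which happens structurally, e.g. for a
   contiguous member block in the middle of the list — the positive
   extreme is chosen, deterministically. Such ties affect only degenerate
   placements and vanish for generic scores.
4. **Permutation p-values.** The null is uniformly random member sets of
   the same size. With the observed ES sign s,

       p = (1 + #{perm: sign match and |ES_perm| ≥ |ES_obs|})
           / (1 + #{perm: sign match}).

   This conditional (same-sign) tail is the convention fgsea uses for
   scores of arbitrary sign, and it is the one that keeps raw p-values
   α-calibrated: conditioning on the observed sign removes the factor-of-two
   size inflation a sign-selected one-tailed test over all permutations
   would incur. An exact-enumeration twin (`gsea_exact_p`) computes the
   same conditional tail over all C(N, k) placements and serves as the
   independent oracle for the permutation route. Permutation draws are
   cached per set size, so equally sized pathways share a null sample.
5. **Multiplicity and calls.** Benjamini–Hochberg adjustment is applied
   within each PC's batch of tested pathways (one correction per GSEA run,
   not pooled across PCs). Pathways at adjusted p ≤ 0.01 are enriched. A
   dataset's enriched count sums calls over its selected PCs, so a pathway
   enriched on two PCs counts twice.

Only *detectable* pathways are tested: ≥ 15 annotated metabolites present
in the dataset (and fewer than the full list, which the statistic requires).
Fifteen members is the practical minimum for adjusted p ≤ 0.01 to be
reachable at all.

## Identifier handling

PubChem CIDs and SIDs are overlapping positive-integer namespaces, and
depositions rarely say which they use. Resolution compares the metabolite's
metadata with both record spaces of a local snapshot: stage 1 fuzzy-matches
the name and all synonyms (both sides' full synonym lists) against the CID
record first, then the SID record, at a normalized-Levenshtein threshold of
95/100 (similarity = 100·(1 − edit distance / longer length), after
case-folding, trimming, and whitespace collapsing); stage 2, reached only
with no name match on either side, requires *both* formula string equality
and mass equality after rounding to 4 decimal places. Unresolved IDs are
unusable and dropped. The threshold, rounding precision, and the
conjunction requirement in stage 2 are configurable; 95 is a conservative
default for fuzzy matching and 4 decimals absorbs the heterogeneous mass
precision of real metadata. Exotic nomenclature normalizers (lipid
shorthand, isotopologues) are pluggable but not built in.

Chained cross-referencing applies directed mapping edges from a snapshot
until a full round adds no identifier. The result equals the directed
reachability closure over the edge table (tested against a brute-force
closure oracle), is idempotent and monotone, and terminates within as many
rounds as there are distinct identifiers. Edges are applied exactly as
given — no symmetric completion — because real knowledgebase
cross-references are asymmetric and incomplete.

## The meta-analysis grid

Six configurations: {original, cross-referenced} identifier sets ×
{ground truth, predictions, union} annotation tables. Per configuration and
dataset the pipeline records the PC-summed enriched count and the set of
uniquely enriched pathways. Gain/loss classification compares ground truth
against a prediction-bearing configuration on unique (dataset, pathway)
outcomes — PC multiplicity collapsed — as lost = gt \ combined, gained =
combined \ gt, unchanged = gt ∩ combined; the three always partition the
union, so |lost| + |gained| + |unchanged| = total exactly, by construction.
The PC-summed counts (with multiplicity) feed the median and Mann–Whitney
comparisons instead; both accountings are computed and reported.
Percentages are rounded half-up to one decimal. Fold changes between
configurations are ratios of median enriched counts, matching the use of
medians throughout; the MCC stratification uses *mean* gain counts per
pathway because the low-MCC stratum's median gain is typically zero.

Per-dataset failures at any stage exclude that dataset with a logged
reason rather than aborting the corpus, mirroring "pipeline completes
without software errors" as a usability criterion. Dataset usability
itself requires ≥ 15 metabolites with compound IDs (in any supported
namespace), matrix minimum ≥ 0, and matrix maximum ≥ 20, checked in a
fixed, reported order (readable → ID count → intensity floor → intensity
ceiling); all boundaries are inclusive.

## What the synthetic generator emulates

`SimulationConfig` defaults define the study regime:

| parameter | default | meaning |
| --- | --- | --- |
| `n_datasets` | 50 | corpus size |
| `n_samples` / `n_metabolites` | 20 / 70 | per-dataset matrix, two balanced groups |
| `n_compounds` | 500 | compound universe |
| `n_pathways`, sizes | 40, 20–28 | all above the 15-member floor |
| `n_planted` | 2 | pathways given a real effect per dataset |
| `gt_dropout` | 0.7 | fraction of true associations missing from ground truth |
| `pred_tpr` / `pred_fpr` | 0.95 / 1e-4 | prediction operating point (realized MCC ≈ 0.9) |
| `xref_completeness` | 1.0 | fraction of true mapping edges in the snapshot |
| `cid_sid_overlap` | 0.3 | fraction of SID integers colliding with CIDs |
| `effect_size` / `noise_sd` | 2.0 / 0.5 log2 units | 4σ planted group shift |
| `zero_rate` | 0.05 | non-detect fraction |

Ground-truth annotations are keyed by each pathway's native knowledgebase
namespace (KEGG → KEGG IDs, MetaCyc → MetaCyc, Reactome → ChEBI), while
predictions are keyed by KEGG and PubChem CID — the identifiers depositions
actually carry (KEGG/PubChem coverage 0.9, MetaCyc/ChEBI 0.05). This
asymmetry, plus dropout, reproduces the mechanism under study: planted
pathways fall below the detectability floor under ground truth alone and
are restored by predictions or (partially) by cross-referencing. Planted
pathways alternate shift direction so that consecutive pathways do not
merge into one broad PC direction; members then concentrate at one extreme
of the PC-1 loading ranking. Prediction quality is parameterized by
(TPR, FPR) with the *realized* per-pathway MCC reported from the actual
confusion counts, because a target MCC does not invert to a unique
operating point. A `low_quality_fraction` of pathways can be given a
degraded operating point to create a quality gradient for the
MCC-stratification analysis.

What the generator does *not* emulate: chromatography/spectral artifacts,
batch effects, realistic chemical nomenclature beyond simple synonym
variants, correlated (pathway-structured) baseline abundances, missing
values other than zeros, and unbalanced or multi-factor designs. Passing
tests therefore show the pipeline's statistical machinery behaves correctly
under its own assumptions, not that those assumptions hold in any given
repository deposition.

## Numerical choices and degenerate inputs

- All-zero intensity matrices and constant (rank-0) log matrices are
  errors; datasets failing any stage are excluded with a reason.
- If a pathway's members all carry zero scores on a PC (possible only with
  degenerate loadings), hit weights fall back to uniform.
- Permutation seeds: one master seed per run; per-(dataset, PC) child seeds
  derive from it through `numpy` seed sequences keyed by the dataset ID, so
  results are independent of corpus processing order and safe to
  parallelize.
- BH adjustment delegates to `statsmodels` (`fdr_bh`); Mann–Whitney U to
  `scipy.stats.mannwhitneyu` (two-sided, tie-corrected); PCA to
  scikit-learn with the full SVD solver. Each is cross-checked in the test
  suite against a brute-force oracle (step-up formula, rank-sum
  enumeration, covariance eigendecomposition).
- Test problem sizes: oracle-equivalence GSEA instances keep
  C(N, k) ≤ 10⁴ for exact enumeration; calibration uses ~25 null datasets
  (several hundred pathway tests); power uses 20 independent seeds; the
  corpus-scale mechanism uses 50 datasets × 3 corpus seeds with 999
  permutations — sizes chosen to give stable Monte-Carlo margins at
  desk scale.

## Known limitations

- The permutation null randomizes set membership, not sample labels;
  correlated metabolites within a pathway are treated as exchangeable with
  the rest of the list, as in all preranked GSEA.
- The ES tie-break (positive on exact magnitude ties) makes a handful of
  degenerate placements sign-asymmetric; complement symmetry and
  list-reversal antisymmetry hold exactly only off those ties (and
  complement symmetry only for the unweighted statistic).
- MCC filtering of predictions (≥ 0.7) is available but off by default;
  the headline grid uses all predictions.
- The mwTab repository format is not parsed directly; datasets enter
  through a strict sectioned-TSV/JSON dialect that a converter can target.
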