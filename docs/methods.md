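# Methods

## Model

`seqharmony` treats interface prediction as a two-group compositional
comparison.  A *pair group* is a multiple sequence alignment whose rows
carry one of two labels: an interacting subgroup H of homodimer chains
(including the query, whose structure supplies ground truth) and a
non-interacting subgroup M of monomer chains.  For every alignment
column *i* the amino-acid frequency vectors p^H_i and p^M_i are computed
per subgroup over the 20 canonical amino acids; gaps and X are excluded
from the counts, and each vector is normalised over its own countable
residues.  Two statistics follow:

* **Entropy** S_i = −Σ_x p_{i,x} log2 p_{i,x}, per subgroup — the
  classical conservation measure, in bits, in [0, log2 20].
* **Sequence Harmony**
  SH_i = −½ Σ_x p^H log2[p^H/(p^H+p^M)] − ½ Σ_x p^M log2[p^M/(p^H+p^M)],
  with 0·log 0 := 0 and residue types absent from both groups
  contributing nothing.  SH ∈ [0, 1]; 0 iff the supports are disjoint,
  1 iff the compositions are identical.

Logarithms are base 2 throughout.  For SH the base is forced by the
normalisation: with p^H = p^M every log term equals log(1/2), so the −½
prefactors produce exactly 1 only in base 2.  Entropy uses the same base
for consistency.  Numerically, SH is clamped to [0, 1] at a 1e-9
tolerance; profile vectors must sum to 1 within 1e-6.

A residue is predicted as interface when its column's SH is at or below
a cut-off (default 0.2, the conventional operating point for this
statistic).  Threshold-free performance is the AUC of the ROC obtained
by ranking residues by −SH, computed via the rank-sum (Mann–Whitney)
formulation with midranks for ties — algebraically identical to the
trapezoidal area under the ROC, which the tests verify independently
with scikit-learn's curve-based route.

## Group construction

Hit lists are ranked by ascending e-value, ties broken by descending
bitscore then subject id (a fixed, deterministic order; multi-HSP
query–subject pairs are collapsed to their first tabular line, and
self-hits dropped).  The **first-cross** rule forms H from the query
plus every homodimer hit ranked strictly above the query's first
monomer hit; that first monomer (the *anchor*) seeds M, which adds every
monomer hit of the anchor ranked strictly above the anchor's first
homodimer hit.  Both subgroups need at least five members, a floor that
guarantees minimal compositional information per column.  The query is
counted inside H: this guarantees the alignment contains the
structure-annotated sequence and makes the minimum-five requirement
well-defined.

Three threshold variants probe robustness:

* **lower-of-two** truncates both subgroups at the smaller of the two
  first-cross e-value cuts (stricter selection, emulating missing data);
* **fixed e-value** cuts both subgroups at one supplied e-value
  (default 1e-10), emulating absent interaction annotation; the anchor
  is still the query's first monomer hit, which also supplies the
  query-to-anchor HSP length used by the filters;
* **mixed** relaxes the rank threshold past the first cross, admitting
  hits of either class in rank order until the next opposite-class hit
  would push the opposite-class fraction of the subgroup above a bound
  (default 20%).  The subgroup seeds (query and anchor) must pass the
  bound for the walk to continue but never switch subgroups, which
  makes a bound of zero reduce exactly to first-cross.  Polluted
  members keep their true class label in the records; subgroup
  membership, not the label, decides the scoring groups.

## Sequence filters

Sequences shorter than 50 residues are removed, exact duplicates are
dropped within each interaction class (first occurrence kept), and
redundancy is reduced by greedy longest-first identity clustering:
records are visited longest first, join the first cluster whose
*representative* they match at or above the threshold, and only
representatives are returned.  Pairwise identity is the number of
identical positions in an optimal global alignment (BLOSUM62, gap open
−10, extend −0.5) divided by the length of the shorter sequence — the
convention of the standard greedy clustering tools, whose word-index
heuristics are deliberately not reproduced (exact pairwise identity is
used instead; a `.clstr` importer lets a precomputed clustering be
injected).  Ten threshold presets (40–100%) parameterise dataset
selections.  Pair groups are further filtered on the query-to-anchor
HSP length and the query sequence length (both inclusive bounds);
raising either bound is monotone — it can only remove groups.

## Evaluation

Positives are interface residues (ASA > 0 and BSA > 0); negatives are
surface plus buried residues by default (`all_classified`), or surface
residues only (`surface_only`) when the contrast of interest is the
solvent-accessible surface.  ASA = 0 with BSA > 0 is rejected as
physically impossible.  Residues lacking an annotation or a defined SH
column are excluded from numerator and denominator everywhere.
Aggregation across pair groups takes arithmetic means (AUC over groups
where it is defined, with the undefined count reported; per-class mean
entropy/SH over groups containing the class).  Class contrasts use the
classical pooled-variance two-sample t-test on per-group class means
(Welch behind a flag); zero pooled variance returns p = 1 for equal and
p = 0 for unequal means rather than NaN.

## Synthetic data

The generator emulates one pair group end to end: labelled sequences,
a gapless alignment, ranked hits and per-residue ASA/BSA annotations.
Defaults are chosen once to mirror a typical pair group in this
problem's corpora: 25 homodimers vs 14 monomers, 120 columns split
roughly 15% interface / 50% surface / 35% buried (typical
globular-protein fractions).  Columns are generated independently:

* buried columns draw one dominant residue (probability 0.9) from a
  three-letter pool shared by both groups — high conservation;
* surface columns draw from a shared five-letter pool with
  Dirichlet(1.5) weights in both groups — diverse but overlapping;
* interface columns, with probability `specificity` (default 0.6),
  use *disjoint* three-letter alphabets for the two groups (planted
  SH = 0); otherwise they behave like surface columns.

Substitution noise (rate 0.05) replaces a residue with a uniform draw
from the same column's group-allowed pool, so planted disjointness is
never violated — at full specificity every interface column scores
SH = 0 exactly.  Annotations assign ASA/BSA consistently with the
column classes; ranked hits are laid out so the first-cross rule
reconstructs the simulated membership exactly, with strictly increasing
e-values (no ties).  The simulated query-to-anchor HSP length grows
monotonically with `specificity`, making HSP filtering the generator's
analogue of selecting more divergent, more informative homolog pairs.
Label pollution replaces a set fraction of each subgroup's members with
draws from the other class's distributions while keeping their subgroup
assignment; the truth table records true and assigned labels, and a
fraction of zero is byte-identical to the clean simulation.

What the generator does **not** emulate: phylogenetic correlation
between columns or sequences (a star-tree at best), alignment errors and
gaps, length variation, rim/core interface structure, and the long-tail
e-value structure of real homology searches.  Passing tests therefore
demonstrate that the statistic and pipeline behave correctly on
compositionally planted signal, not that real proteomes carry signal of
this strength.

## Design choices and degenerate inputs

* Gaps are not a 21st symbol; the sums run over the 20 amino acids
  only.  Columns where either subgroup is all-gap get no SH and are
  excluded from prediction and evaluation.
* Sequence counts are unweighted; redundancy is controlled upstream by
  identity filtering.
* Pair groups are not deduplicated across queries by default (an
  optional collapse of identical member sets exists), and each
  evaluation joins scores to annotations via the 1-based index of the
  query's ungapped residues.
* The pipeline consumes externally produced alignments (aligned FASTA);
  alignment itself is an import boundary, keeping the package free of
  subprocess dependencies.
* Determinism: all simulation randomness flows from one integer seed;
  writers use fixed column order and six-significant-digit floats, so
  re-running a configuration reproduces outputs byte-identically.

## Problem sizes used in the test suite

Replicated synthetic experiments use 40–100 replicates of the default
pair group (39 sequences × 120 columns), which keeps the full suite
fast while leaving Monte-Carlo means stable to well under the margins
asserted (e.g. mean AUC ≈ 0.85 against a 0.6 bound).  Oracle
equivalence checks run on instances small enough for exhaustive
enumeration (≤ 12 residues for pair-counting AUC, ≤ 8 sequences for
clustering).

## Known limitations

Exact pairwise-alignment identity clustering is quadratic in the number
of sequences and not meant for corpus-scale inputs; real ASA/BSA
annotations must be supplied in the package's TSV carrier (no structure
or assembly parsing); and the method inherently requires a
non-interacting homolog group — families without annotated monomeric
relatives cannot be scored.
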