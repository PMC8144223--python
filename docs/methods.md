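# Methods

## Scope and model

`epibind` implements the prediction core of a murine MHC class I
neoantigen workflow: given an epitope table (peptides with qualitative
binding labels and source-protein accessions), a protein FASTA, and
optionally a missense-variant table with expression values, it

1. builds a labeled fixed-length peptide dataset,
2. trains a bidirectional-LSTM binary binder on balanced, augmented
   batches,
3. smooths threshold calls with a BLOSUM62 majority vote, and
4. ranks mutant peptide windows as neoantigen candidates.

Upstream NGS processing (read QC, alignment, variant calling, effect
annotation, expression quantification) is out of scope; the package starts
from the tables those tools produce.

## Dataset construction

Qualitative labels are binarized: `Positive High`, `Positive
Intermediate`, `Positive Low` (and plain `Positive`) map to 1, `Negative`
to 0, anything else is rejected. Each positive epitope is located on its
source protein by Smith–Waterman local alignment under BLOSUM62 with
affine gaps (open 11, extend 1; a gap of length k costs `11 + (k-1)`).
The aligner is an exact three-state Gotoh DP written in-package so that
tie-breaking is deterministic (the left-most optimum under row-major
scanning); its scores are cross-checked in the tests against
`Bio.Align.PairwiseAligner` on random sequence pairs. An entry is accepted
only when the alignment covers the whole epitope without gaps at ≥ 90%
identity; otherwise it is dropped as unmappable and counted.

Positive examples are **all** length-L windows of the protein that fully
contain the mapped epitope span (L ∈ {8, 10, 12}; 12 by default, the
length that performed best for H-2K^b-style data). The number of such
windows has the closed form `min(s, n−L+1) − max(1, e−L+1) + 1` for a span
(s, e) on a length-n protein. Negative examples are length-L windows tiled
(stride configurable, default 1, deduplicated by string) over the regions
of the same proteins that overlap no known epitope span by even one
residue. A string emitted as a positive window is never also emitted as a
negative. Entries labeled `Negative` contribute no windows at all —
negatives come exclusively from the remaining sequence of positive-bearing
proteins. No prevalence is imposed on the dataset; at the default stride
the synthetic study lands near 1:26 positive:negative, the heavy-imbalance
regime the method is designed for.

The train/test split (default 10% test) is stratified by label and
performed on **unique peptide strings**, so an identical peptide occurring
in two proteins can never leak across the split. Coordinates are 1-based
inclusive everywhere outside the encoders.

## Network and training

Peptides are one-hot encoded over the fixed alphabet
`ACDEFGHIKLMNPQRSTVWY` (stored in every checkpoint; loading fails loudly
on mismatch). The classifier is three stacked bidirectional LSTM layers
followed by three dense layers with two intermediate dropouts; the head is
a single sigmoid unit (mathematically a 2-way softmax) trained with binary
cross-entropy. Defaults: LSTM units (64, 64, 64), dense (64, 32, 1),
dropout (0.3, 0.3), Adam with learning rate 1e-3, batch 32. All layers are
implemented in NumPy with hand-written backpropagation; gradient
correctness is enforced by finite-difference checks in the test suite, and
everything (initialization, sampling, augmentation, dropout) draws from
one seeded generator, so a fixed seed reproduces training bit for bit on a
single thread.

Because positives are rare, training never iterates over the raw dataset.
Each step draws a fresh **on-batch balanced** batch: exactly
`round(batch × virtual_prevalence)` positives (default prevalence 0.5)
sampled with replacement, the rest negatives. Sampled positives pass
through BLOSUM62 augmentation: `n_sub` positions (default 2) are drawn
uniformly without replacement and each is replaced by a uniformly drawn
residue whose substitution score is ≥ `tolerance` (default 0); a position
with no allowed replacement is left unchanged. Negatives are never
augmented. Since no BLOSUM62 off-diagonal entry reaches 4, tolerance 4
degenerates to the identity, which the tests verify by exhaustive scan.
One "epoch" is `steps_per_epoch` such batches (default: enough to cover
the training set once). Early stopping monitors validation loss on a
stratified 10% hold-in split with patience 5 and restores the best
weights; it is disabled (validation_fraction 0) where exact step budgets
matter.

Grid search uses stratified k-fold cross-validation (k = 5 by default).
The fold partition is a function of (labels, k, seed) only and is shared
across all configurations, which compete on mean fold AUC ROC. A grid of
c configurations trains exactly c × k models.

## Postprocessing and evaluation

A call is `score ≥ threshold` (default 0.5). The majority vote builds the
peptide's L single-substitution neighbors — position i replaced by the
BLOSUM62-most-similar residue, ties broken alphabetically (so L → I, not
M) — scores them, and flips the original call only when a **strict**
majority of neighbor calls disagrees; a 6–6 tie on a 12-mer keeps the
original call. The vote operates on neighbor calls, not scores, and is
idempotent. Union ensembling of two call vectors is an elementwise OR,
which can only increase sensitivity.

Metrics: AUC ROC is the rank statistic with ties counted half (checked
against a brute-force all-pairs oracle); PR AUC is the non-interpolated
average-precision step sum, whose chance level equals the prevalence;
accuracy, PPV, sensitivity, specificity and F1 (harmonic mean of PPV and
sensitivity) come from the confusion matrix of calls. Single-class label
vectors leave the AUCs undefined (None) but keep the threshold metrics.

## Variant peptides and ranking

Only rows whose VEP consequence contains `missense_variant` are kept;
`"R/Q"` amino-acid fields are parsed into ref/alt and malformed rows are
skipped with a warning. The candidate window applies the substitution and
takes the length-L window starting at `pos − ⌊L/2⌋`, clamped into
`[1, n−L+1]` — shifted at the termini, never padded, so no residue is ever
fabricated; for an unclamped 12-mer the mutation sits at 0-based offset 6.
A reference-residue mismatch between the table and the FASTA is a hard
error reporting expected vs found. Candidates are ranked by probability
(descending, sequence string as stable tie-break); FPKM is attached for
the user's inspection — a gene missing from the expression table gets 0.0
with a warning — and is never used in the ranking itself.

## Synthetic ground truth

The generator emulates the *shape* of the real inputs with a knowable
truth. Binding is an anchor motif over an 8-mer core: positions 5 and 8
must carry a residue from {W, Y} and {C, M} respectively — echoing the
anchor-position biology of H-2K^b-like molecules without claiming its real
motif. The default background distribution is uniform over the 16
remaining residues, i.e. it assigns probability zero to the anchor
residues. That choice makes the label a deterministic function of
sequence: background can never form a motif, so a noise-free dataset is
perfectly separable (oracle AUC exactly 1.0), which is what turns the
end-to-end training test into a genuine parameter-recovery check.
Optional entry-level label noise (`noise_rate`) flips implanted entries to
`Negative` before windowing, propagating the way assay noise would.

Default scale: 200 proteins of 300–500 residues, 500 implanted epitopes,
stride-1 negatives — about 2.5k positive and 75k negative windows,
prevalence ≈ 1:26. What passing tests on this data do **not** show:
robustness to real assay noise, overlapping/nested epitopes from competing
assays, non-canonical residues, or motifs whose residues also occur in the
background; real binding data are noisier and the attainable AUC is
accordingly lower.

## Numerical and design choices

- Alignment ties: left-most optimum; acceptance requires full-query,
  gap-free, ≥ 90%-identity alignments.
- Rounding of batch positive counts: round-half-up. Note this guarantees a
  positive in every batch only when `virtual_prevalence ≥ 0.25` (for
  batch ≥ 2); smaller prevalences can legitimately produce all-negative
  batches.
- Epitopes longer than L are dropped (they cannot be reframed into
  L-mers), as are entries with unresolvable accessions or non-canonical
  residues (X, U, B, Z, J, O); all drops are counted in `BuildStats`.
- The end-to-end benchmark (`epibind.benchmark.synthetic_end_to_end`, also
  driven by `scripts/acceptance.py`) trains the default architecture for
  5 epochs × 150 steps of batch 32 with no early stopping — a deliberately
  small budget that the separable synthetic task saturates; real data
  would use the full default budget (20 epochs, patience 5).
- Checkpoints are single-file `.npz` archives holding weights, the full
  parameter dict, the alphabet string and a version tag.

## Known limitations

- Majority-vote smoothing votes with the model's own (imperfect) neighbor
  calls, so it can occasionally flip a correct call that sits near the
  decision boundary; on the synthetic benchmark this amounts to at most a
  handful of peptides in several thousand.
- The binder accepts exactly one peptide length per model; multi-length
  scoring requires one model per length.
- Training is single-threaded NumPy: ~15–20 ms per batch-32 step at
  default sizes. Fine for the intended dataset scale, not for
  proteome-wide pretraining.
- One `VariantPeptide` is emitted per (accession, position, alt) triple;
  transcript-to-protein aggregation is left to the caller.
- Accession resolution (e.g. UniParc ↔ UniProt) is not performed;
  epitope/variant accessions must match the FASTA.
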