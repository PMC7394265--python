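# Methods

This note documents the models, parameter choices and numerical decisions
behind `sorfpipe`, and what the synthetic benchmark does and does not show.

## Coordinates and region arithmetic

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
columns are converted at the I/O boundary. Region partitioning assigns each
genomic position exactly one of three labels with precedence
exonic > intronic > intergenic. Intronic intervals are the gaps between
consecutive exons *of the same transcript*, minus exonic bases of any other
transcript; bases inside a gene span that are neither exonic nor intronic
under that definition (e.g. annotation gaps) fall back to intronic so the
three sets always tile the sequence — an invariant asserted in the tests.
Gene spans for the intergenic complement come from `gene` features when
present, else `mRNA`, else `CDS`, which keeps the partition robust to
sparse annotations. No buffer is trimmed around gene boundaries: nothing in
the workflow depends on UTR margins, and trimming would silently shrink the
search space.

## ORF model

An ORF is ATG…stop with the stop included in its genomic interval;
`n_codons` counts residues only, and the ≤ 80-codon cap is applied to the
residue count (nucleotide span ≤ 243 with the stop). Only ATG is accepted
as a start. Any codon containing N is neither start nor stop and closes the
open frame, so no ORF spans ambiguous sequence. The default
`longest_per_stop` mode emits, per (frame, stop) pair, the most-5′ ATG
whose ORF lies inside the `[min_codons, max_codons]` window; a long open
stretch with an in-window internal ATG therefore still yields a small ORF
rather than being discarded with its over-long leader. `all_starts` mode
(every qualifying ATG) exists for sensitivity analyses. The default
`min_codons = 10` damps the flood of tiny chance ORFs while keeping the
11-residue scale of the shortest interesting peptides recoverable; it is
configurable down to 1.

The Kozak flag is a strand-aware motif check — purine at −3 of the A of
ATG and G at +4 — labelled `undetermined` when the context runs off the
sequence. It is a stand-in for translation-initiation evidence and is
reported as metadata, never used as a filter.

## Hexamer coding potential

The second predictor is a hexamer log-odds model: with counts
`c_cod(h)`, `c_non(h)` over all overlapping 6-mers (step 1, 6-mers with N
skipped) and pseudocount α = 1,

    s(x) = mean_h∈x [ log p̂_cod(h) − log p̂_non(h) ],
    P(coding | x) = logistic(a·s(x) + b).

Per species, the coding corpus is the annotated (spliced) CDS set and the
noncoding corpus the intergenic sequence. The calibration (a, b) is
**cross-fitted**: each corpus is split in two, each half is scored in
240-nt windows under the table trained on the opposite halves, and the 1-D
logistic regression (class-balanced) runs on those out-of-sample scores.
This matters: a 4096-parameter table estimated from a few tens of
kilobases flatters its own training sequences by ~0.3 nats of mean
log-odds, so an in-sample calibration places the decision boundary between
the *inflated* coding scores and the noncoding scores and then rejects
genuinely coding out-of-sample input. The 240-nt window matches the length
scale of the ORFs the model will judge. Degenerate corpora (identical
coding and noncoding input) yield an all-zero table and calibration
(1, 0), so every probability is exactly 0.5. The 0.5 threshold is applied
per ORF, boundary inclusive.

## Consensus, pooling, homology

Consensus defaults to exact interval equality between the two predictors'
outputs — the strictest reading of "overlap" and the only one that needs no
tuning; `shared_stop` (same stop codon, scanner's start wins) is available
because independent predictors may pick different ATGs for one gene. On
pooling, duplicate intervals collapse with the annotation record winning.

The homology screen is protein-level local alignment (BLOSUM62, gap open
11, extend 1 — the conventional short-protein search setting) of pooled
peptides against all annotated proteins; since candidates are already
translated, a six-frame translated search would add nothing. The engine is
Biopython's C `PairwiseAligner`; its scores are verified exactly against an
independent brute-force affine-gap DP in the tests, and the reported
alignment (first optimal traceback) is deterministic for fixed input. The
hit filter keeps alignments with query coverage ≥ 2/3 **and** identity
≥ 30% (both boundaries inclusive); the alternative reading — remove only
hits failing both — is implemented as `OR_retain` and selectable. No
E-value model is applied, so for very short queries the filter is easily
satisfied by chance and the homology status should be read as a label, not
a significance statement.

## Clustering and conservation

Records are de-duplicated on exact nucleotide sequence (peptide when no
nucleotide is available), preferring annotation-derived survivors. The 70%
clustering is greedy longest-first, first-fit against cluster
representatives — the scheme of incremental clustering tools — with a
canonical sort (length descending, id ascending) that makes the outcome
independent of input order. Identity is *identical columns of the optimal
global alignment / length of the shorter sequence*. The global alignment is
substitution-matrix-scored (BLOSUM62, affine 11/1) rather than unit-cost:
an unpenalised minimal-edit alignment degenerates to a longest-common-
subsequence count when lengths differ, which lets a random 10-residue
peptide reach "70% identity" to a 70-residue one by scattering matches —
empirically this produced large spurious cross-species clusters, and gap
penalties eliminate it. A residue-multiset intersection bounds the
identical columns of any alignment from above and prunes most candidate
comparisons cheaply. Member-to-representative identity ≥ threshold is
asserted post hoc in the tests.

A cluster is conserved when its members span ≥ 2 distinct species.
Conservation breadth (species in cluster / species total) is additionally
summarised in quarter bins.

## JTT distances, NJ, bootstrap

The JTT rate matrix is assembled from the published exchangeability counts
and equilibrium frequencies, normalised to one expected substitution per
site per unit time, and diagonalised once through the π-symmetrised form
`B = D^{1/2} Q D^{-1/2}` for numerically stable `P(t) = exp(Qt)`. The
pairwise distance maximises `Σ_sites log[π(a) P(t)_{a,b}]` over
t ∈ [0, d_max] (bounded Brent, tolerance 1e-7); columns containing a gap
or non-standard residue are excluded per pair, fewer than 10 comparable
columns raises an "unreliable" warning (the value is still returned), and
a boundary optimum reports the saturation cap d_max = 5. This estimator is
unbiased and achieves the information bound in simulation (sd ≈ 0.027 at
t = 0.3 with 500 sites), which also means no estimator of this quantity
can be materially tighter at that length.

Neighbor joining is the Saitou–Nei algorithm with deterministic tie-breaks
(smallest index pair in the current working order); negative branch
lengths are clamped to zero with the deficit moved to the sibling edge, so
path lengths are preserved and additive matrices are reconstructed exactly
(verified to 1e-9). Cluster alignments for tree building are
representative-anchored: each member is globally aligned to the
representative and projected onto its columns (insertions relative to the
representative are dropped). This avoids an external multiple-alignment
dependency; an externally computed alignment can be supplied in FASTA.
Bootstrap resamples alignment columns with replacement once per replicate,
re-estimates all distances and the tree, and reports each internal
bipartition's frequency; a fixed seed makes reruns bit-identical. Trees
are written as Newick with six-decimal branch lengths and supports as
internal node labels; rooting against an outgroup is a display choice, not
part of inference.

## Synthetic benchmark

`PlantSpec` defaults define the smoke conditions: 3 species × 200 kb,
25 multi-exon ordinary genes and 3 annotated sORF genes per species, 10
hidden sORF families of 11–80 codons planted in intergenic (70%) or
intronic (30%) space, per-copy substitution rate 0.05/site, GC 0.45.
Coding sequence (genes and planted families alike) is reverse-translated
with a skewed codon-usage table (one preferred codon per amino acid at
weight 8), which gives the hexamer model a learnable signal analogous to
real codon bias. Mutations are codon-aware with 2:1 synonymous bias and
never create stops or touch the start/stop, so peptide identity decays
more slowly than nucleotide identity and within-family identity stays
above the 70% threshold at the default rate. A stop codon is written
immediately 5′ of every planted start so the planted ATG is the most-5′
in-frame start for its stop and a longest-per-stop scanner recovers the
planted interval exactly — making exact-coordinate recall a fair score.
Everything derives from one `numpy` generator seed; outputs are
byte-reproducible.

What the benchmark does **not** emulate: indels within conserved families,
repeat content, GC heterogeneity, alternative splicing, annotation errors,
and amino-acid composition bias in real proteomes. Passing it shows the
machinery is correct and calibrated under its stated noise model, not that
recall on real genomes will match.

Recovery scoring: a family counts as recovered iff some conserved cluster
contains its copies (matched by exact genomic interval) from ≥ 2 species
and no other family's copies; conserved clusters mixing families count as
impure. Losses at the default rate are dominated by families whose
ancestral sequence genuinely scores below the 0.5 coding threshold —
correlated across species because the ancestor is shared — which is the
expected behaviour of a correct classifier near its decision boundary, not
a pipeline defect. Reverse-strand "shadow" ORFs of planted copies may form
additional conserved clusters; they are genuinely conserved sequence and
are not counted as impure.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` run the smoke conditions (three
seeds plus a negative control), 200 random sequences for the scanner
oracle, 100 peptide pairs for the alignment oracle, 500 + 500 training and
test sequences for the classifier, 100 replicates × 500 sites for JTT
recovery, and bootstrap at 20–50 replicates inside pipeline runs (the
production default is 1000); these sizes keep a full verification run in
the low minutes on a single CPU while leaving every statistical conclusion
stable.
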