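# Methods

`curliscan` annotates curli functional-amyloid (csg) systems in bacterial
genomes: it finds homologs of the Csg protein families with profile HMMs
built from curated seed alignments, locates minimalistic curli repeats in
candidate subunits, classifies the operon layout of each genome, and
compares Csg protein trees with 16S-like marker trees. This note records
the models, the numerical conventions, and the design choices made where
the design was genuinely open.

## Pairwise and progressive alignment

Global alignment is Needleman–Wunsch with affine gaps. A gap of length
*L* costs `GOC + (L−1)·GEC`; terminal gaps are charged, so the score is a
true global optimum. This convention had to be fixed by the package: gap
"costs" are quoted in the literature on ClustalW's internal scale, which
is not fully specified, so score-optimality under the stated convention is
the contract rather than output-equivalence with ClustalW. Defaults are
BLOSUM62 with GOC 15 / GEC 1 for protein alignments (BLOSUM45 is available
for remote-homology work); repeat-region consensus alignment conventionally
uses GOC 50 / GEC 1 to keep the short repeat units gap-free.

Ties are broken deterministically: prefer an aligned pair, then a gap in
the second sequence, then a gap in the first. The progressive stage
aligns profiles along a neighbor-joining guide tree built from pairwise
p-distances; profile columns are scored as the average substitution score
over all non-gap residue pairs. Sequence weighting and iterative
refinement are deliberately out of scope — only the pairwise optimum is
contractual, and the tests verify it against exhaustive enumeration.

## Profile HMMs

Models follow the classic match/insert/delete architecture. Alignment
columns with gap fraction below one half become match states. Match
emissions are background-weighted pseudocount estimates,
`(counts + w·bg)/(n + w)` with weight `w = 1` by default — simple and
reproducible where Dirichlet mixtures would add opaque constants at this
scale. Transitions are counted from each row's implied state path with
add-one smoothing; insert runs flanked by a delete are collapsed onto the
direct move, since the plan7 topology has no D↔I transitions.

Search is local with free flanks: unmodelled prefix/suffix residues score
zero bits, entry into any match column costs `−log2(n_match)` bits, exit
after any match column is free, and every scored path passes through at
least one match state. Scores are log-odds in bits against the
background (uniform 1/20 by default); the ambiguity letter X scores zero
bits wherever it appears. Viterbi and forward are exact under this path
space — both are tested against brute-force path enumeration on small
models.

Score statistics are empirical rather than analytic: `calibrate` sets the
cutoff at the upper `(1−fpr)` quantile of best-hit scores on decoy
sequences, and reported e-values are the surrogate
`n_targets · 2^(−bit score)`. Within the iterative curation loop the
default `fpr` is 0.0025 on 400 decoys — effectively the maximal decoy
score — deliberately harder than a one-shot search threshold, because an
accepted hit feeds back into model training and a single false inclusion
can snowball across iterations.

The combined CsgA/B subunit model is trained solely on repeat regions:
every 22-residue minimalistic-repeat window of an accepted subunit becomes
one (trivially aligned) training row. Aligning *concatenated* repeat
regions was rejected: with 2–22 units per protein the row lengths differ
by an order of magnitude, the alignment becomes gap-dominated, and the
majority-gap rule would discard most columns.

## Minimalistic curli repeats

The repeat is a 22-residue window with literal Q/G/N anchors at offsets
6, 8 and 11 (X₆QXGX₂NX₁₀). The scanner tests **every** window start, so
overlapping ("superimposed") windows are all reported; a left-to-right
consuming search would miss them. Note the anchor geometry itself
constrains superimposition: two window starts 2 or 3 apart are impossible
(their anchor patterns collide), the smallest compatible offsets being 1
and 4. Wildcard positions accept any residue including X; anchors must be
literal. A protein is flagged functional only with ≥ 2 windows —
subunits with zero or one repeat are treated as non-functional.

Consensus profiles of aligned repeat sets use inclusive conservation
tiers (≥ 50%, ≥ 80%, = 100%), with gaps counted in the denominator and
integer arithmetic at the boundaries. Overlapping windows are merged into
maximal regions (`extract_repeat_regions`) only where region sequence is
needed; motif counts always refer to windows, since published repeat
counts enumerate motif instances, not merged regions.

## Operon architecture

Operons are maximal runs of same-contig, same-strand genes with
intergenic gaps ≤ 200 bp (configurable; no published numeric rule exists,
so the default is stated and logged). Two transcription units are
*divergent* when they point away from a shared intergenic region of at
most 1000 bp. The classifier distinguishes the five canonical layouts
(divergent csgBAC/csgDEFG; the same pair co-oriented; divergent pair with
csgD transcribed alone; single csgBAEFG operon with divergent csgD; one
operon holding everything) and falls back to `other`. Classification uses
only csg-labelled genes, is invariant under coordinate translation and
contig reverse-complementing, and tolerates interleaved non-csg genes.

CsgA and CsgB can be told apart only in Gammaproteobacteria with a
csgBAC-like layout: the repeat gene proximal to the transcription start is
the nucleator (csgB), the next the major subunit (csgA); everywhere else
the ambiguous label csgA/B is kept, with a confidence flag.

## Iterative curation

Each round builds one model per family from the current homolog
alignment, searches every proteome, and accepts hits by an explicit
two-clause rule replacing manual curation: bit score above the calibrated
cutoff AND (≥ 1 previously accepted csg homolog within 5 genes on the
same contig, OR — for subunit candidates — ≥ 2 repeat windows).
Corroborating neighbors are restricted to members of probative families:
CsgD belongs to a very large regulator family and is searched and
reported but never used as evidence, and unvetted same-round co-hits
cannot vouch for each other (subunit hits qualified by their repeats are
the one exception, since their evidence is intrinsic). When one locus is
claimed by several family models the best-scoring model wins; losers are
logged as out-competed. Hits in genomes without annotations are held as
"unplaceable" — accepted on their intrinsic evidence and flagged, never
silently dropped, which is the behaviour needed for plain-FASTA
metagenome scans. Every decision is logged with its evidence.

The loop realigns each family's non-redundant accepted set (exact
duplicates removed), rebuilds, and stops when a round accepts nothing
new; the homolog set grows monotonically and `max_iterations` (10) bounds
the loop, returning a warning flag rather than raising on non-convergence.
The homolog set is initialized with the seed alignment rows — they are the
curated database — so a proteome containing only the seeds is a fixed
point reached in one round.

Validation reports use the classic hits / correct hits / missing hits
schema with percentages rounded half-up to integers.

## Trees and congruence

Distances are uncorrected p-distances over columns where neither row has
a gap. Neighbor joining follows the Saitou–Nei Q-criterion with ties
broken by label order; additive matrices are recovered exactly (verified
to 1e-9 against random additive trees), and negative branch-length
estimates are clamped to zero and flagged. Congruence between a Csg tree
and a 16S tree is summarized by the Robinson–Foulds distance (symmetric
difference of non-trivial bipartitions) plus per-genus monophyly — an
explicit surrogate for the visual "similar overall topography" judgment,
which has no published statistic. Monophyly is evaluated on unrooted
bipartitions and is therefore rerooting-invariant. 16S sequences must be
supplied pre-aligned (or aligned with `progressive_msa`); rRNA-specific
aligners are out of scope.

## The synthetic study

The generator emits what the method consumes — per-genome protein FASTA
and GFF, seed alignments, truth tables — with the statistical structure
the method assumes. Its defaults are the study conditions every
end-to-end figure in this package refers to:

* **10 genomes, 5 operon classes × 2** (genera A–E, one class per genus).
* **Subunit proteins**: 2–22 repeat units (csgA drawn from 4–22, csgB
  4–6, ambiguous subunits 4–12), each unit with literal anchors and
  flanks 30% identical to a family consensus. Flank residues exclude
  Q/G/N, so the planted window starts are *exactly* the motif matches and
  truth is exact rather than a lower bound.
* **Accessory families** CsgC–CsgH as point-mutated variants of fixed
  consensus sequences (110–230 aa): genus consensus 15% from the family
  consensus, genome copies 3% from the genus consensus, seed variants 5%.
* **Two-tier divergence ladder** in csgD and csgG: GenusB/C carry a mid
  lineage 50% diverged from the ancestral consensus; GenusD carries a
  remote lineage derived from the mid lineage with residual ancestral
  identity reduced to an evenly spaced 18%. Spreading the residual
  evenly leaves no long ancestral-like run, so seed-trained models score
  the remote members below the calibrated cutoff while mid-broadened
  models recognise them — the iterative search demonstrably needs (and
  gets) a second round. These shifts were calibrated against the scoring
  model so the ladder's margins hold across seeds.
* **Split genus**: the second GenusC genome's csgF derives from a distant
  lineage (25% from the family consensus), so the Csg tree splits GenusC
  while the 16S-like tree does not — the classic signature that genus
  monophyly flags.
* **Decoys**: 30 i.i.d. background proteins per genome (80–300 aa),
  rejection-sampled to contain no repeat window; two sit immediately
  beside the csg cluster so the neighborhood clause is actually
  challenged. 400 separate decoys calibrate the score cutoffs.
* **16S-like markers** are equal-length (pre-aligned) four-letter
  sequences with genus structure and no split.

What the generator does **not** emulate: insertions/deletions within
family proteins (alignment columns map 1:1 to consensus positions),
compositional bias of real proteomes (decoys are uniform i.i.d.),
paralogy beyond the subunit family, gene fragmentation and pseudogenes,
and nucleotide-level evolution (contigs are coordinate bookkeeping only —
no stage of the method reads DNA). Passing tests therefore show the
machinery is correct and the statistical logic sound under these
conditions; they do not certify recall on real, indel-rich proteomes.

## Problem sizes and numerics

The standard study (10 genomes, ≈360 proteins, 400 calibration decoys)
runs the full pipeline in about 1.5 minutes; the brute-force oracle
batteries use sequences ≤ 6 residues and models ≤ 3 match states, where
exhaustive enumeration is feasible. All randomness flows from a single
integer seed through `numpy` generators; reruns are byte-identical.
Floating-point conventions worth naming: emission/transition rows must
sum to 1 within 1e-9; the HMM text format round-trips probabilities
exactly (repr precision); conservation tiers and validation percentages
use integer arithmetic at the boundaries; alignment and DP tracebacks
recompute candidate values so tie-breaking is exact, not
tolerance-based.

## Known limitations

* Viterbi reports one best-scoring segment per target; multi-domain
  (repeat-distributed) hits are summarized by that segment.
* The empirical e-value surrogate is honest about its provenance but not
  comparable to Gumbel-fit e-values from other tools.
* The curation rule is a mechanized surrogate for expert judgment; its
  two clauses are configurable and logged, but no claim is made that
  they reproduce any particular manual curation.
* Operon calls come from gene geometry alone; promoters, terminators and
  transcriptomic evidence are out of scope.
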