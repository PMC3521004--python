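# curliscan

Annotation of **curli functional-amyloid (csg) systems** in bacterial
genomes and metagenomes.

Curli are extracellular amyloid fibrils — best known from *E. coli* —
whose major subunit CsgA polymerizes on the nucleator CsgB, assisted by
the accessory proteins CsgC–CsgG (and, in many Alphaproteobacteria, the
csgA/B-adjacent gene csgH). Subunit homologs diverge so fast that plain
sequence search misses them: what is conserved is a *modular repeat
structure* — tandem 22-residue units written **X₆QXGX₂NX₁₀**, with
literal glutamine, glycine and asparagine anchors — plus the gene
neighborhood the subunits sit in. `curliscan` turns that observation into
a reproducible pipeline:

* **profile HMMs** (match/insert/delete states, log-odds bit scores,
  local "free-flanking" Viterbi/forward search) built from curated seed
  alignments, with decoy-calibrated score cutoffs; the combined CsgA/B
  model is trained solely on repeat regions;
* an exhaustive **minimalistic-repeat scanner** that reports overlapping
  ("superimposed") windows and summarizes per-protein repeat
  architecture (a protein with ≤ 1 repeat window is non-functional);
* **operon reconstruction** and classification into the five canonical
  csg layouts (divergent csgBAC/csgDEFG, the co-oriented variant,
  detached csgD, single operon with divergent csgD, single operon);
* an **iterative search-and-curate loop** — build models, search, accept
  hits by an explicit neighborhood/repeat rule, realign, rebuild — run to
  convergence, with every decision logged;
* **neighbor-joining trees** and congruence statistics (Robinson–Foulds
  distance, genus monophyly) between Csg protein trees and 16S-like
  marker trees;
* a **synthetic-genome generator** that plants all of the above with
  known truth, so the entire method is testable end to end offline.

See `docs/methods.md` for the models, conventions and design rationale.

## Worked example

Generate two synthetic genomes with planted csg systems, build a CsgF
model from the emitted seed alignment, and search one proteome:

```console
$ curliscan simulate --seed 42 --n-genomes 2 -o fixtures
wrote 2 genomes to fixtures
$ curliscan hmm-build fixtures/seeds/csgF.aln.fasta -o csgF.hmm
built csgF.aln: 130 match states
$ curliscan hmm-search csgF.hmm fixtures/genomes/G01.faa --cutoff-bits 20 -o hits.tsv
1 hits >= 20.0 bits
$ cat hits.tsv
target_id	bit_score	start	end	evalue_surrogate
G01_0002	261.66	0	129	6.34e-78
```

The single hit is the planted csgF gene (`fixtures/truth.tsv` confirms
locus `G01_0002`, family csgF): 261.66 bits of log-odds support over the
whole 130-column model, with a decoy-calibrated e-value surrogate of
6.3e-78. Repeat scanning on the same proteome flags exactly the planted
subunits as functional amyloid candidates:

```console
$ curliscan repeats fixtures/genomes/G01.faa -o repeats.tsv
scanned 37 proteins
$ grep True repeats.tsv | head -2
G01_0005	6	15,37,59,81,103,125	0	True
G01_0006	8	23,45,67,89,111,133,155,177	0	True
```

`G01_0005` carries six 22-residue repeat windows starting every 22
residues (starts 15, 37, 59, …), none overlapping — the end-to-end
organisation typical of subunit proteins — and is therefore functional
(≥ 2 windows). The full pipeline (`curliscan pipeline --seeds … --genomes
… -o results/`) runs the iterative curation loop and writes
`homologs.tsv`, `validation.tsv` (hits / correct hits / missing hits
rows), `architecture.tsv`, `repeats.tsv`, Newick trees and a decision
log.

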