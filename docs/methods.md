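# Methods

## The problem

Protein sequences of non-model species in public databases are often
predicted computationally and can be incomplete — typically truncated at
the N- or C-terminus. When a well-curated orthologue from a related
species exists, and RNA-Seq data for the species of interest is
available, the orthologue can be used as a *bait* to fish the target's
true coding sequence out of a de novo transcriptome assembly, and the
annotated sequence can be validated or replaced.

`orthorefine` implements the sequence-side of that workflow on a
pre-computed contig set: translated homology search, reciprocal best-hit
(RBH) validation, ORF-based protein reconstruction, refinement
quantification, and an outlier statistic that flags probably-misannotated
orthologues in identity tables.

## Translated search and scoring

A bait protein is aligned to all six reading-frame translations of every
contig with full Smith–Waterman (affine gaps). We deliberately use exact
local alignment rather than a seeded heuristic: the package targets
desk-scale problems (one target or a few hundred baits against one
assembly), where correctness and determinism matter more than whole
proteome throughput. Externally computed alignments in the 12-column
tabular format can be supplied instead for large runs.

* Substitution matrix: BLOSUM62 (the NCBI variant including `B`, `Z`,
  `X`, `*`). Stop codons in a translated frame act through the matrix's
  `*` column (−4 against residues, +1 against `*`); frames are not split
  at stops.
* Gap model: a length-*k* gap costs `gap_open + k·gap_extend` with
  defaults 11/1 (so the aligner's first-gap-position score is −12).
* Statistics: bitscore `(λ·S − ln K)/ln 2` with the published gapped
  BLOSUM62 parameters λ = 0.267, K = 0.041, and E-value
  `m·n·2^(−bitscore)` where *m* is the query length and *n* the total
  residue count of the translated database. No edge-effect length
  correction is applied; the contract is ordering fidelity, not exact
  replication of any particular search engine's E-values. The default
  significance cutoff is E ≤ 1e−4.
* One HSP — the single optimal local alignment — is kept per (contig,
  strand, frame); there is no HSP chaining or sum statistics, because the
  pipeline only consumes best-hit ordering. Ties after (bitscore,
  E-value) break on lexicographic subject id for determinism.

Subject coordinates are mapped from frame protein space back to 1-based
inclusive forward-strand nucleotides (`sstart > send` on the minus
strand), matching the tabular interchange dialect. Internally all
coordinates are 0-based half-open.

## Reciprocal best hits

For each bait the *n* best distinct contigs (default 1) are carried to a
reverse search against the reference protein set. The reverse query is
the whole contig by default (blastx-style validation); a `longest_orf`
mode searches with the contig's longest ORF peptide instead, and the mode
used is recorded in the result. A bait is an RBH iff the **top-ranked**
contig's best reverse hit is the bait itself; lower-ranked contigs are
reported but do not affect the flag, so the detection rate is a
per-protein, single-best-hit statistic. Reverse-hit identity is matched
on the exact sequence id; accession mapping is the caller's concern.

## ORF calling

All six frames are scanned. A complete ORF runs from the first ATG of a
stop-delimited segment through the stop. Because short-read assembly
contigs need not span whole transcripts, partial ORFs are reported and
flagged: 5′-partial (no ATG before the frame's first stop, runs from the
frame start), 3′-partial (ATG with no downstream stop), and — a case we
chose to include — both-ends-partial (a frame with neither ATG nor stop,
i.e. a fragment internal to a CDS; excluding it would make refinement
from mid-CDS fragments impossible). Nested internal ATGs are not reported
separately. The minimum length default is 100 aa, the common long-ORF
convention; partial ORFs are eligible as the "longest ORF" by default
(switchable), with ties broken complete-before-partial, then + strand,
then smaller start. No coding-potential model is applied: selection is
purely by length.

## Refinement quantification

Directional pairwise identities follow the Ensembl orthology convention:
after a global, end-gap-penalised affine alignment of target *t* and bait
*b*, `target identity = 100·matches/len(t)` and
`query identity = 100·matches/len(b)` — full ungapped lengths as
denominators, not alignment columns (the aligned-columns identity is kept
separately for tabular-format compatibility). Among co-optimal global
alignments the one maximising the match count is used; this is computed
exactly by scaling the substitution matrix by 2¹⁶ and adding +1 on the
diagonal, which makes the optimiser's objective `2¹⁶·score + matches`
without leaving C-level alignment code.

Refinement of an annotated target is the decrease in
`|target identity − query identity|` from (old vs bait) to (refined vs
bait); the report stores signed and absolute values, since the flagging
rule uses the absolute difference while distribution plots are usually
signed. When no prior annotation exists the fallback compares local
alignment coverage of the refined sequence and of the bait.

For visual inspection a center-star multiple alignment is produced
in-package (center = maximal summed pairwise score; merged under
once-a-gap-always-a-gap). Its quality is sufficient for eyeballing
refinement success; unaligned FASTA can be written for an external MSA
tool when publication-grade alignment is needed.

## Flagging poorly annotated orthologues

Input is a per-gene × species table of target/query identities. The
signed difference (target − query) signals length discrepancies: 98/80
gives +18 (orthologue probably truncated). Per species, genes with
`|diff| > mean(|diff|) + 2·sd(|diff|)` are flagged; the statistic is
computed on absolute differences with the sample (n−1) SD (both choices
switchable — the convention is ambiguous in the field, and absolute
differences make the one-sided truncation signature symmetric). A
cross-species filter then keeps genes flagged in exactly one species
among genes with records in all species; genes missing records somewhere
are excluded rather than treated as unflagged (absence of evidence).
Note the rule's arithmetic implies a lone outlier can only exceed
mean + 2·SD of the contaminated sample when n ≥ 6.

## Assembly metrics

`assembly_metrics` reports contig count, max/mean length, the number of
contigs with an ORF ≥ `min_aa`, and the mean percent of ORF-bearing
contigs covered by their longest ORF — the coding-potential indicators
commonly used to characterise transcriptome assemblies. Coverage uses the
longest ORF per contig, consistent with the pipeline's representation
choice; replicating any particular assembly-QC tool's exact computation
is a non-goal.

## Synthetic data generator

The generator provides ground-truthed inputs for every stage:

* **Ortholog families.** Ancestral CDSs are uniform over sense codons
  (ATG start, one stop). Species orthologues substitute exactly
  `round((1−t)·L)` codon positions with codons of a different non-stop
  amino acid, so realised protein identity is `(L−d)/L` — within half a
  residue of the target *t*. The start codon is never mutated and no
  indels are introduced by default: planted CDSs stay complete ORFs, and
  the identity arithmetic is exercised through truncation instead.
* **Assemblies.** Expressed genes (Bernoulli, default p = 0.7, matching
  the typical fraction of protein-coding genes detectably expressed in a
  tissue) emit one guaranteed full-length contig plus fragments with
  normal lengths (default mean 800 nt, sd 200, floor 300 — a plausible
  fragment-length scale for short-read assemblies of CDSs in the 900–1800
  nt range); strands flip with probability 0.5. Unexpressed genes emit
  nothing.
* **Poor annotations.** A fraction of genes (default 20%) has 10–40% of
  residues removed from the N-terminus (the characteristic failure mode
  of predicted gene models).
* **Paralogs.** Optional always-expressed paralog genes at a configurable
  identity (default 70%) probe RBH confusion.

Everything derives from one seed; identical configs give byte-identical
fixture directories.

What the generator does **not** emulate: sequencing errors, chimeric or
misassembled contigs, alternative splicing, UTRs (contigs are pure CDS
substrings), indel divergence, or expression levels beyond on/off.
Passing the recovery tests therefore demonstrates the correctness of the
search/ORF/identity machinery on clean data, not robustness to assembly
artefacts.

## Validation experiment sizes

The self-contained validation (tests and `scripts/acceptance.py`) uses
problem sizes chosen to exercise every code path at desk scale: 200
random instances for each oracle-equivalence check (queries ≤ 12 aa,
contigs ≤ 60 nt for the quadratic reference DP); 50 genes of 300–600 aa
with 20% truncated for end-to-end recovery (ortholog identity 1.0 — the
delta-identity arithmetic is exact only noise-free); 100 genes of
100–200 aa for the expression-dependence of the RBH detection rate at
p ∈ {0.3, 0.7, 1.0} (the statistic is length-independent on planted
data); 20 replicates for paralog confusion control; and 25 genes × 3
species for flagging recovery.

## Numerical and degenerate-input choices

* Translation implements the standard genetic code; codons containing N
  render `X` unless all four substitutions agree; trailing partial codons
  are dropped. `U` maps to `T` on ingest and other IUPAC ambiguity codes
  map to `N` with a logged warning (real assemblies contain them).
* Local alignments with no positive-scoring pair return raw score 0 and
  an empty alignment.
* Contigs shorter than one codon yield no frames (warning, not error);
  an empty search result is valid everywhere downstream and surfaces as
  "no significant hit" with non-zero exit status in the CLI.
* Threshold comparisons in flagging are strict (`>`), so an all-equal
  table flags nothing.
* The E-value formula underflows to 0.0 for very strong hits; ordering
  then falls back to bitscore, which is why bitscore leads the sort key.

## Known limitations

* The Karlin–Altschul parameters are fixed for BLOSUM62/11/1; other
  matrices align correctly but their E-values use the same λ/K.
* The center-star MSA is not iterative; long insertions in several
  non-center sequences can produce staggered gap columns.
* Reverse-search E-values use the nucleotide query length for *m*;
  this differs from translated-length conventions by a constant factor
  and does not affect ordering.
* One-to-one orthology is assumed in the flagging tables; one-to-many
  relations should be filtered upstream.
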