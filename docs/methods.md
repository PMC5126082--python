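# Methods

This note documents the models, conventions and parameter choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Homology screen

Candidates are found by optimal local alignment (Smith–Waterman with
affine gaps) of each proteome sequence against an annotated reference
panel, using BLOSUM62 with gap open 11 / extend 1 — the classic protein
search parameterization. Raw scores are converted to bit scores with the
gapped Karlin–Altschul parameters published for BLOSUM62 11/1
(λ = 0.267, K = 0.041, from the precomputed table shipped with NCBI
BLAST), and E = m·n·2^(−S′) with the total panel residue count as the
database length n. A protein is retained when its best hit has
E ≤ 1e−5 **and** bit score ≥ 100; both defaults are the standard family
screen cutoffs. Ties among equal-scoring best hits break to the
lexicographically smallest reference id, and results are ordered by
query id, so the screen is invariant to input order. No low-complexity
masking is applied; the test decoys are residue-shuffled instead.
Alignment itself runs through Bio.Align.PairwiseAligner; a brute-force
enumeration oracle in the test suite pins the scores.

## Progressive alignment

Guide distances are fractional shared 3-mers (1 − shared/min), the guide
tree is neighbor joining on those distances, and profiles merge
leaf-to-root by affine-gap Gotoh DP on the profile–profile expected
substitution score (gap and X columns contribute zero). This is a
deliberate simplification of CLUSTALW-style pairwise-alignment guide
trees: it is fast, deterministic, and sufficient for the downstream
consumers, which only need homologous columns within a subfamily to line
up. Alignment polish (column identity against a curated MSA) is *not* a
goal and is not tested.

## Distances, NJ and bootstrap

Distances from an MSA use pairwise deletion (gap columns dropped per
pair); p-distance is the default and a Poisson correction (−ln(1−p)) is
available — which model underlies published AQP NJ figures is usually
unstated, and on within-family divergences the two give the same
topology. A pair with zero comparable columns is an error (or, inside a
bootstrap replicate, falls back to the replicate maximum so the
replicate stays usable).

Neighbor joining is the standard Saitou–Nei agglomeration with the
textbook Q-matrix; ties break to the lowest (row, column) pair, and
negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch (this affects patristic distances and hence
nearest-reference fallbacks, which is why it is fixed rather than left
to a library default). On additive matrices the tree reproduces the
input distances to 1e−9 (tested).

Bootstrap resamples alignment columns with replacement; the support of
an internal edge is the percentage of replicate NJ trees containing the
same bipartition. Replicate r uses an independent generator seeded
`seed + r`, so supports are reproducible under any execution order.

## Subfamily assignment

A query's subfamily comes from a clade rule on the unrooted tree of
candidates + references: among all edge bipartitions, take the smallest
side containing the query and at least one reference; if every reference
in (all minimal-size) such sides belongs to one subfamily S, call S with
that edge's bootstrap/100 as support. Otherwise fall back to the nearest
reference by patristic distance; a tie between references of different
subfamilies leaves the query `unclassified` — by construction a chimera
placed equidistantly between two subfamilies gets no call rather than an
arbitrary one.

## Selectivity residues

"Careful visual inspection of the alignment" is formalized as position
transfer: the query is globally aligned (Needleman–Wunsch, same scoring
scheme) to the reference with the highest global identity among panel
members of its subfamily, and every annotated reference position is read
off the aligned query column; positions opposite gaps report the missing
marker `-`. Alignments under 15% identity are refused ("reference too
distant"). Transferred NPA sites are validated against the query's
actual N-P-x triplets: the nearest N-P-x within ±5 residues of the
transferred site wins, so small local misalignments cannot misplace a
motif, and variant third residues (NPV, NPT, NPL, NPS) are reported as
found with a per-motif variant flag.

**NPA–NPA spacing** is the number of residues strictly between the two
triplets (start-to-start offset minus 3). The published 108–128 range
never states its counting convention; this one is fixed here and the
bundled panel annotation places every reference at 116 under it.

**Substrate signatures** (urea, H₂O₂, CO₂, boric acid) are allowed-set
vectors over the SDP positions in listed order, with tokens like `ILV`
or `F/I/L` parsing to {I,L,V} / {F,I,L}. A substrate matches when every
available SDP residue is allowed and ≥80% of signature positions are
available; the matched fraction is reported for diagnostics. The nine
SDP coordinates are anchored to the reference panel's annotation, since
signature strings alone do not name alignment coordinates.

## Protein properties

* **GRAVY**: mean Kyte–Doolittle hydropathy; X is excluded from the mean
  (logged), B/Z are not accepted by the record types.
* **MW**: sum of average residue masses + one water, in kD; X is fatal
  because its mass is undefined.
* **pI**: Henderson–Hasselbalch net charge — positive groups N-terminus,
  K, R, H; negative groups C-terminus, D, E, C, Y — is monotone
  non-increasing in pH, so the root is found by bisection on [0, 14] to
  0.001 pH by default. The default pKa set is the EMBOSS one and the
  table is a swappable dataclass: published pI columns computed with
  other web tools will differ in the second decimal, so table *fixtures*
  (not recomputed values) carry the published numbers, and the family
  summaries operate on fixture values.
* **TM segments**: 19-residue sliding-window mean hydropathy with cutoff
  1.6; maximal runs of above-cutoff window centers expand to their
  windows' extent and merge on overlap. This is a transparent heuristic,
  not an HMM: it reliably counts the six TM blocks of the synthetic
  templates but is not expected to reproduce TMHMM calls on real
  proteins.

## Genome context

Gene span is **end − start** (not +1): that is the convention under
which the published per-gene lengths (863 bp shortest, 4382 bp longest)
reproduce exactly from the printed coordinates, and it is kept
deliberately even though GFF3 lengths are inclusive. Intron lengths are
the gaps between consecutive exons; exon+intron totals equal span+1
under 1-based inclusive arithmetic (property-tested on random models).

Tandem arrays chain same-chromosome, same-subfamily genes whose starts
lie within 100 kb with at most one intervening non-family gene —
an approximation of the MCScanX criterion, which needs the full gene
complement; both parameters are exposed. Note the published 8-gene
tandem list omits one member of a four-gene cluster that this criterion
includes, so array membership, not the count 8, is the tested surface.
Segmental calls take externally supplied homologous anchor pairs, chain
them per chromosome pair by longest increasing subsequence (ascending
and descending passes, so inverted blocks count), and flag AQP pairs
inside chains of ≥3 anchors. Unplaced scaffolds are binned as
`unplaced` in density reports; genome-wide density is reported as Mb
per gene and its reciprocal.

## Promoters

The promoter is the 1-kb window upstream of the annotated gene start —
taken as the transcription start site, since upstream annotations rarely
distinguish the two — read on the coding strand (minus-strand genes get
the reverse complement of the downstream-in-plus-coordinates window),
truncated with a warning at chromosome edges. Scanning reports **every**
match of an IUPAC consensus, overlapping included, on both strands by
default; minus-strand hits are reported at the promoter coordinate of
their leftmost base, and palindromic motifs therefore produce two hits
per locus (deduplication available but off by default). The bundled
cis-element table (Box-4, G-Box, I-Box, ACE, ARE, HSE, ABRE, MBS, LTR,
W-box, TC-rich repeat, TCA-element, AuxRR-core, ERE, GARE-motif,
circadian CAANNNNATC) uses PlantCARE-style consensus strings recorded in
a versioned data file; only the circadian consensus is fixed by the
source analysis, so no test depends on the other strings — planted-motif
recovery is checked against a generation-time oracle scan instead.

## Expression clustering

The dissimilarity is 1 − uncentered correlation on raw FPKM vectors
(identical to cosine distance), computed over pairwise-complete entries;
an all-zero vector is undefined and such genes are dropped from
clustering with a log message, mirroring heatmap practice. No log
transform by default (a log2(x+1) option exists). Linkage is unweighted
average via scipy; a brute-force agglomeration oracle checks merge
order and heights. Cluster labels after a k-cut are renumbered by first
appearance in dendrogram leaf order so outputs are deterministic.
Published cluster narratives depend on SRA-derived FPKM values that are
not reproducible from printed material, so recovery is tested on planted
structure instead.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed); per-element
substreams (`default_rng([seed, indices…])`) keep one gene's data stable
when another is added. The **reference panel itself is synthetic** —
twelve sequences on a canonical 6-TM scaffold with subfamily-consensus
ar/R, Froger and SDP residues at hand-annotated coordinates — because
characterized AQP sequences cannot be bundled; the panel is rebuilt
bit-for-bit by `python -m mipkit.panel_builder`.

Defaults mirror the shape of a small family survey: proteins at 8–15%
divergence from templates (substitutions never inside mapped positions;
indels ≥6 residues away from them), toy genomes with 1–6 introns per
gene (GT..AG bounds, ≥76 bp), tandem arrays ~4 kb apart, 1-kb promoters
at 40% GC, and a 40-gene × 8-tissue FPKM matrix with four planted
clusters peaking ~25× over baseline with 5% relative noise (the
strong-separation regime).

Consequently, passing recovery tests show the pipeline's *inference
machinery* is correct under its own generative assumptions; they do not
show robustness to real-data phenomena the generators omit: rate
heterogeneity and codon structure in evolution, domain architecture
variation, alternative splicing, promoter composition bias, expression
heteroscedasticity, or batch effects.

## Numerical choices and degenerate inputs

Deterministic tie-breaks throughout (NJ lowest index pair, best-hit
lowest subject id, merge lowest cluster indices, cluster labels by leaf
order). Bisection tolerance 0.001 pH; NJ additivity asserted to 1e−9;
distance symmetry to 1e−12. Empty proteomes screen to empty results;
single sequences refuse alignment; k outside [1, n] refuses to cut;
zero-length promoters refuse to scan; fixture files are checksummed
(SHA-256) and refuse to load when edited.

## Problem sizes

Tests and the acceptance script run on deliberately small instances —
tens of sequences of ~275 residues, 24–40-gene expression matrices,
8-gene toy genomes, 10 seeds per recovery suite — chosen so the whole
suite completes in well under a minute while still exercising every
code path at the divergence levels the recovery criteria name.
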