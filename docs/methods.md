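# Methods

This note documents the models, conventions and numerical choices behind
`mitocompare`, in the spirit of a methods supplement: what each statistic
assumes, which knobs matter, and what the synthetic data do and do not
establish about real genomes.

## Coordinate model

Internal coordinates are 0-based half-open on the forward strand; GenBank
I/O converts to and from 1-based inclusive. A feature crossing the
circular origin is stored as two spans — `(x, L)` then `(0, y)` in
transcription order — plus a `wraps_origin` flag, and all length
arithmetic on circles is modular. Introns implied by multi-span CDS
annotations (`join(...)` coordinates) are synthesized as explicit intron
features with `parent` set; explicitly annotated introns take precedence
when both describe the same gap. Gene names are canonicalized through a
versioned alias table (`data/gene_synonyms.tsv`, matched
case-insensitively); unmatched names pass through verbatim and keep their
annotated category, so third-party ORFs of any length are retained.

## Composition and region partitioning

Skews follow AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); `N` is excluded
from every GC and skew denominator, and a zero denominator yields an
explicit undefined marker rather than 0. Region partitioning assigns every
nucleotide exactly one label with precedence coding-exon > RNA > intron >
intergenic. Two conventions matter and are fixed here:

* intron-encoded ORFs (homing endonucleases) count as **intronic**, not
  coding — an ORF whose every span lies inside an annotated intron is not
  painted as coding; free-standing ORFs count as coding (a flag excludes
  them for sensitivity analyses);
* overlapping gene envelopes share nucleotides by the precedence rule, and
  overlap bookkeeping (`intergenic_and_overlaps`, negative gaps) is
  reported separately so the partition remains a partition.

The contribution rate of region *r* to a pair's size difference is
C_r = (r_large − r_small)/(size_large − size_small) × 100%. Because the
four regions tile both genomes, ΣC_r = 100% exactly, with individual rates
free to be negative or to exceed 100%. Equal genome sizes are an error,
not a zero.

## Alignment

The pairwise global aligner is Needleman–Wunsch/Gotoh with affine gaps,
match +1, mismatch −1, gap open −5, gap extend −1, where a gap run of
length k costs `open + (k−1)·extend`. Traceback tie-breaking is fixed
(diagonal, then gap in the first sequence, then gap in the second) so
alignments are bit-reproducible. Coding sequences are aligned codon-aware:
the translations (table 4) are aligned and nucleotides threaded back, so
gaps always fall on codon boundaries. Multiple alignment for the
supermatrix is center-star progressive alignment to the longest sequence —
an approximation to a full MSA that is exact for the indel-free sequences
the simulator produces and adequate for the conserved core genes this
package targets.

## Evolutionary rates

K2P uses pairwise deletion: columns with a gap or ambiguity are dropped
per pair, and P (transitions) and Q (transversions) are fractions of the
remaining columns; the correction raises a saturation error, reporting P
and Q, whenever a log argument is non-positive.

Ka/Ks is classic NG86: per-codon synonymous site counts S_c as the
synonymous fraction of the nine single-nucleotide neighbors (changes to
stop codons count as nonsynonymous), sites averaged over the two
sequences, observed differences resolved by equal-weight averaging over
mutational pathways. Pathways passing through a stop codon are excluded;
when every pathway does, all are included with stop steps counted as
nonsynonymous (the convention the classic method leaves open — fixed and
frozen here). Proportions are Jukes–Cantor corrected; Ka/Ks is undefined
(not zero, not infinite) when Ks = 0. The method is deliberately the
simple counting estimator, not a maximum-likelihood ω: it is exactly
specifiable, fast, and sufficient for the purifying-versus-positive calls
made on core mitochondrial genes.

## Intron position classes

A cox1 intron is identified by its insertion offset — the number of
spliced-CDS nucleotides 5′ of it — and projected onto a reference CDS
through the codon-aware alignment at nucleotide resolution (group I
introns need not sit at codon boundaries). An insertion point facing a
reference gap projects to the nearest reference nucleotide on the 5′ side;
alignment identity below 30% leaves the intron unmapped with a warning.
Position classes are exact-position equivalence classes by default; a
merge window (default 0) exists for noisy annotations. P-labels count
reference **nucleotides**, not alignment columns, so labels can shift by
small offsets against figures produced under the other convention. The
common/rare call defaults to "at least one fifth of species"
(k ≥ ⌈n/5⌉); a strict more-than-one-fifth rule (5k > n) is selectable,
since published wordings differ between the two.

The bundled `data/reference_cox1.fasta` is a **synthetic** stand-in with
the length and composition of a basidiomycete cox1; real analyses must
pass the true reference CDS explicitly.

## Gene arrangement

Arrangement analysis uses the 17-gene set (15 core PCGs + rnl + rns);
tRNAs are excluded. Orders are canonicalized by rotating the anchor gene
(default cox1) to the front and, if the anchor lies on the minus strand,
reading the circle in the other direction — so rotation and full reversal
of a genome never register as rearrangement. The breakpoint distance
counts signed circular adjacencies of one order absent from the other
(adjacency (x, y) ≡ (−y, −x)); it is a metric on canonical orders.
`changed_genes` lists genes with any differing signed neighbor — one
operational definition of "genes varied in arrangement"; published counts
based on unstated criteria are not promised to match.

## Repeats

Interspersed repeats: shared 11-mers off the trivial self-diagonal (both
strands) are clustered per diagonal, extended without gaps under an X-drop
rule (match +1, mismatch −2, drop 8), and reported at ≥ 40 bp and ≥ 85%
identity, with overlapping hits merged best-identity-first. The E-value
threshold of a BLAST-based protocol is replaced by these explicit cutoffs,
chosen so that the 47–246 bp, 87–97% identity hits typical of small fungal
mitogenomes are always reportable. k-mers occurring > 100 times are
dropped as low-complexity. The scan is linear: repeat copies crossing the
circular origin are not detected (a known limitation; origins
conventionally sit in intergenic DNA).

Tandem repeats: for each period p ≤ 500, maximal runs of `s[i] == s[i+p]`
(interruptions ≤ 3 merged) define candidate arrays, refined against a
column-majority consensus. An array is reported when its total length
exceeds 10 bp, it spans ≥ 2 copies, ≥ 80% of positions match the
consensus, and its alignment score (+2 per match, −7 per mismatch — the
Tandem Repeats Finder weights, with TRF's default threshold 50) passes.
The score threshold is what keeps the finder silent on random DNA: the
bare >10 bp/2-copy rule alone fires constantly on i.i.d. sequence at high
periods. Nested periodicities (p, 2p, …) collapse onto the smallest
period. Repeat fractions are computed on the **union** of hit intervals —
overlapping hits are never double-counted.

## Supermatrix and trees

The supermatrix concatenates per-gene codon-aware alignments of spliced
(hence intron-free) CDSs in fixed gene order, with a partition table of
half-open column ranges; taxa missing any gene are dropped with a warning.
Neighbor joining is the canonical Saitou–Nei algorithm with deterministic
tie-breaking by taxon label (merged nodes inherit the smaller member
label), so the tree is invariant to input row order; negative branch-length
estimates are clamped to zero and flagged. Trees are unrooted; an optional
outgroup rooting is display-only. NJ on a K2P matrix is a desk-scale
stand-in for Bayesian/ML inference — PHYLIP/NEXUS and RAxML-style
partition writers are provided so external inference can run on the same
matrix.

## The synthetic clade generator

`simulate_clade` builds an ancestral genome — the bundled reference cox1,
14 further core PCGs at realistic lengths (153–1,998 bp), rnl/rns
(2,970/1,413 bp), 23 tRNAs of 71–88 bp — and evolves it down a (given or
random) tree. Defaults: 35 kb genomes, GC 30%, mean branch length 0.05
proposals/site, ω = 0.2 per gene. Coding sequences evolve by a
proposal–acceptance substitution process: synonymous proposals accepted
with min(1, 1/ω), nonsynonymous with min(1, ω), stops never created, so
the realized Ka/Ks tracks the per-gene target. Non-coding features mutate
per-site. Intergenic filler is generated at the GC level that lands the
whole genome on target. Gene order evolves by per-branch inversion and
transposition counts; introns are inserted at planned reference-cox1
offsets (exact by construction, since coding evolution is substitution-only
— the *projection* machinery is exercised on diverged sequences, but
indel-robustness of the projection is established by dedicated fixtures,
not by the generator); repeats are planted into intergenic gaps, with an
error before generation when the budget does not fit. All randomness flows
from the single spec seed through named substreams, making output
byte-deterministic. The ready-made `apiotrichum_like_spec()` mirrors the
shape of a 19-genome comparison: two focal sister species of 34,648 and
38,096 bp, seventeen background taxa spread from 25 kb to 178 kb, a shared
orthologous cox1 intron in the focal pair, common and rare intron classes
in the background, and cob/rps3 simulated near the positive-selection
boundary.

What passing tests on synthetic clades establish: the analysis code
recovers exactly what the generator planted (regions, Pcls, arrangements,
repeats, ω within sampling error). What they do not establish: robustness
to the messiness of real annotations — inconsistent feature keys, missing
introns, trans-spliced genes — beyond the canonicalization layer, nor
alignment quality at divergences far above ~30%.

## Numerical and testing choices

* Ka/Ks parameter-recovery tests pool Ka and Ks over 12 replicate
  500-codon pairs at 0.03 proposals/site before taking the ratio; a single
  pair at that length has too much sampling variance for a ±25% interval,
  and pooling is the standard variance reduction. At much higher
  divergence NG86's pathway averaging biases ω > 1 estimates toward 1,
  which is a property of the estimator, not a bug.
* The default codon-weight table boosts ATT/TTA/TTT/TAT/AAA/AAT above the
  other AT-only codons so the generator's intended top-six ranking is
  strict rather than tie-broken by sampling noise.
* Start/stop codons are reported verbatim — a GTG start is never
  "corrected" to ATG.
* Undefined quantities (skew with zero denominator, Ka/Ks at Ks = 0,
  saturated distances) are explicit `None`/error states, never silent
  zeros.

## Known limitations

* No de-novo annotation: gene, intron and tRNA calls are taken from the
  input records.
* Center-star alignment degrades on highly length-variable genes; it is
  not a substitute for a profile MSA at deep divergences.
* The tandem finder's consensus refinement assumes the period detected at
  the seed stage; rotationally offset copies of the same array are
  deduplicated, not merged into a single refined model.
* Origin-crossing repeat copies and origin-crossing intron-bearing genes
  are outside the repeat finder's and the simulator's reach,
  respectively.
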