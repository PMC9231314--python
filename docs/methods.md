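# Methods

This note records the models, parameter choices, and numerical conventions
behind `bsfvirome`, and what the synthetic-data tests do and do not
establish.

## Coordinate conventions

Internally every genomic location is a 0-based half-open interval. The
printed coordinate dialect of curated EVE tables (`SEQID:START-END`) is
mapped so that the element's span equals `END - START`; this is the only
reading consistent with the table's own stated span extremes (148 and
3750 nt), and the printed pair is therefore stored verbatim as a half-open
interval. Tabular homology-hit files (BLAST/DIAMOND `outfmt 6`) use 1-based
inclusive coordinates and are converted on ingestion.

## Translated homology search

The built-in search is a BLASTx-style pipeline reduced to its core: six-frame
translation (standard code, stops as `*`, partial codons dropped), exact
amino-acid k-mer seeding, and ungapped bidirectional X-drop extension under
BLOSUM62. Defaults:

| parameter | default | rationale |
| --- | --- | --- |
| `kmer_k` | 3 | at ~60% nucleotide identity a degraded viral fragment retains only ~30–40% amino-acid identity; the probability of an exact 4-mer surviving in a 100–200 aa fragment is materially below 1, while a 3-mer seed is near-certain. |
| `min_score` | 75 | ungapped local-score statistics (Karlin–Altschul, lambda ~0.32 for BLOSUM62) put the expected number of random hits of score >= 75 for a ~100 kb x 10-protein search well below one; verified empirically (100/100 seeded random replicates hit-free). |
| `min_aln_len_aa` | 20 | excludes trivially short segments. |
| `xdrop` | 40 | an alignment at ~35% amino-acid identity routinely contains score dips of 20–30 between conserved patches; a 40-point drop threshold lets extension bridge them. X-drop only controls how completely true optima are found — the score distribution of random data, and hence the false-positive rate at `min_score`, is unchanged. |

No E-value is computed: the stand-in does not model database-size statistics,
so ranking and thresholding use raw score and alignment length. Externally
ingested tabular hits keep their own E-values. Per (contig, subject) only the
best-scoring hit of each overlapping cluster is kept; ties break by higher
score, then higher percent identity, then lexicographic subject id.

On windows up to 2 kb every reported score is verified in the test suite
against an independent ungapped Smith–Waterman oracle (the reported ungapped
score can never exceed the local optimum, gapped or not).

## EVE calling

* **Merging.** Hits of the same viral family on the same contig merge
  transitively when the inter-hit gap is *strictly* less than 50 nt
  ("closer than 50 bp"); overlapping hits always merge. Merging is strand-
  and frame-agnostic because an EVE decays by mutation after integration and
  its reading frames scramble; this is config-switchable. Merged candidates
  are checked against a brute-force union-find clustering oracle.
* **Host-protein screen.** A candidate is discarded iff a translated search
  of its nucleotide sequence against the host proteome yields any hit at the
  same thresholds. Disabling the screen always yields a superset of calls.
* **Contamination filter.** A candidate is discarded iff it has fewer than
  50 nt of contig sequence on *both* sides — i.e. the "EVE" occupies
  essentially its whole contig, the signature of co-sequenced contamination
  rather than integration. One-sided contig-edge EVEs are retained.

## Orthology assignment

Loci are anchored on one reference assembly (the chromosome-level one, in
the motivating use case): each reference EVE seeds a locus, numbered per
family in (contig, start) order. A non-reference EVE joins a same-family
reference locus iff

1. the two EVE sequences align globally at >= 98% nucleotide identity
   (match +1, mismatch −1, gap −2; identity = identities / alignment
   columns — a deterministic aligner standing in for interactive
   read-mapping tools), and
2. each of its flanks shares an exact substring of >= 50 nt with the
   reference 20 kb window centred on the reference EVE (clipped at contig
   edges, which keeps the EVE centred rather than re-anchoring).

The 98% bar is applied to the EVE sequences only; flank placement is a
separate condition. The exact-substring flank test was chosen over a
global-alignment match count because two unrelated random flanks of a few
hundred nucleotides already share ~25% of alignment columns by chance,
whereas an exact shared 50-mer has essentially zero false-positive
probability and is order-independent and deterministic. EVEs failing both
conditions against every reference locus stay unplaced (`np`). Assignment is
a partition (each EVE in exactly one locus or `np`), invariant to the order
of non-reference assemblies, and raising the identity bar can only shrink
loci — all property-tested.

## Virus annotation and alignment preparation

ORFs run ATG → stop (stop included in the interval; length counts coding
codons) on all six frames, starting at the first ATG after the previous
in-frame stop. The two longest non-identical ORFs are labelled GAG (5'-most
on the plus strand) and POL (3'-most), the canonical totivirus layout;
contigs are orientation-normalised first so the longer (POL) ORF is 3'. A
length tie keeps positional labels and logs a warning. A contig is a
near-complete genome iff strictly longer than 5 kb *and* both labels are
present.

Alignment trimming applies two rules, in an order chosen to make the
operation idempotent: first the alignment is restricted to the span between
the first and last columns with >= 50% occupancy (the "trimmed at both
ends" rule — the 50% end bar is a documented choice, config-exposed);
inside that span a column is kept iff its occupancy is at least the 10%
threshold, inclusive, so one residue among ten rows survives exactly.
Defining the end trim as a span restriction (rather than "strip until a
dense column is met, then filter") is what guarantees `trim(trim(x)) ==
trim(x)`: the surviving leading/trailing columns are themselves >= 50%
occupied. Concatenation is keyed by taxon, not row order, and records
per-part column ranges for partition files. Alignment inference itself
(MAFFT-class) and tree inference are deliberately external.

## Quantification

TPM is computed over the supplied feature set only (`rate = count/length`,
rescaled to 10^6 per sample), matching the convention in which every
published sample column sums to one million. Ratios against the
housekeeping feature are rounded half-even at 3 decimals, which reproduces
all ten published ratio cells from the packaged TPM fixture. Multi-placed
reads count toward their single best placement and are dropped on ties —
the abstraction of an external aligner-plus-filter step. The minimal SAM
text reader exists for count ingestion only (QNAME/FLAG/RNAME/AS tag).

## Synthetic data: the stated world

The generator fixes one world and the tests measure the pipeline against it:

* Host background: i.i.d. uniform nucleotides. No repeats, no composition
  structure — the screens under test are homology- and interval-based.
* EVE degradation: substitutions only, placed at exactly
  `round((1-identity)*len)` distinct positions, so realized identity is
  controlled to within rounding. No indels (indel tolerance is exercised by
  hand-built cases, not the generator).
* Reverse translation: uniform codon choice per residue.
* Orthologous copies: the mutated EVE sequence is shared verbatim across
  carrying assemblies, and with conserved flanks the surrounding sequence
  (±20 kb, clipped) is shared too.
* Reads: error-free, single-end, uniform start, exact per-feature counts.
* The canonical three-assembly scenario plants nine loci (fragment lengths
  120–250 aa, nucleotide identities 0.60–0.90, presence patterns 3/3, 2/3
  and 1/3 assemblies) plus one whole-contig (flankless) insert and one
  host-decoy insert whose source protein is copied into the host proteome.
  Host proteins are translations of randomly chosen host genome stretches,
  sampled away from planted EVEs so the proteome stays genuinely host-like.

A green recovery test therefore establishes that the pipeline finds
substitution-degraded single-copy insertions in neutral sequence at the
stated identities, and that the two discard paths fire for their designed
cases. It does not establish robustness to repeats, segmental duplications,
indel-riddled EVEs, assembly errors, or read error/bias — real-data
behaviour beyond the model.

Determinism: all randomness flows through `numpy.random.default_rng(seed)`;
rerunning any generator with the same seed reproduces outputs
byte-identically (FASTA wraps at 80 columns; FASTQ qualities constant).

## Scale of the checked properties

The empirical false-positive calibration (100 seeded replicates of a 100 kb
genome against 10 proteins, all hit-free at defaults) takes ~90 s and is
run out of band; the packaged test suite runs a reduced 20-replicate, 30 kb
version of the same check so the default `pytest` run stays fast. All other
acceptance-grade properties run at their stated sizes (1,000 random merge
sets, 20 orthology worlds, 200 random alignments).

## Known limitations

* The search is ungapped and frame-local: a frameshifted EVE is found as
  separate hits and healed only by the 50 nt merge rule.
* No E-value calibration; thresholds are raw-score based and documented
  above rather than reconstructed from any external tool's settings.
* The flank-match test requires an exact 50-mer; heavily diverged flanks
  (older integrations) would need a relaxed matcher.
* Locus labels are systematic (reference-coordinate order), not curated;
  published label sets may order differently.
* TPM denominators cover only the supplied features — values are
  comparisons within that set, not transcriptome-wide abundances.
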