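# bsfvirome

In-silico virome analysis for insect genome and transcriptome assemblies,
built around the black soldier fly (*Hermetia illucens*) use case: insects
reared at industrial scale whose viral threats are still largely
uncharacterised. The package answers two questions from public sequence data
alone — *which viruses infected this host's ancestors* (endogenous viral
elements, EVEs, fossilised in the genome) and *which virus is infecting it
now* (exogenous virus contigs in transcriptomes, quantified against a
housekeeping gene).

## What it computes

**EVE discovery.** Host genome contigs are searched in all six reading
frames against a family-labelled viral protein database (exact amino-acid
k-mer seeding, ungapped X-drop extension under BLOSUM62 — a built-in
stand-in for BLASTx/DIAMOND; external 12-column tabular hits are drop-in
replacements). Hits from the same viral family closer than 50 bp merge into
one candidate. Candidates matching a host protein are discarded as false
positives; candidates with fewer than 50 nt of host sequence on *both* sides
are discarded as sequencing contamination. Surviving calls get summary
statistics (counts per family, span range, chromosome occupancy).

**Orthology placement.** Two EVEs in different assemblies are the same locus
when their sequences align globally at >= 98% nucleotide identity *and* both
flanks of the candidate match the reference copy's 20 kb window (an exact
shared substring of >= 50 nt per side). Loci are labelled per family in
reference-coordinate order (T1, T2, ... for *Totiviridae*, PR1, ... for
*Parvoviridae*, and so on).

**Exogenous virus triage and quantification.** Transcriptome contigs are
annotated for ORFs; contigs longer than 5 kb with the totivirus GAG+POL
(capsid + RdRP) layout are near-complete genomes, the rest partial
fragments. Protein alignments are occupancy-trimmed (columns kept when at
least 10% of sequences have a residue) and concatenated for external tree
inference. Viral RNA load is expressed in TPM over the supplied CDS set,

```
rate_i = count_i / length_i        TPM_i = 10^6 * rate_i / sum_j rate_j
```

and reported as the ratio TPM(viral CDS) / TPM(housekeeping gene), rounded
half-even to 3 decimals.

Every stage is testable without downloads: `bsfvirome.synthetic_data`
generates host assemblies with planted, degraded viral fragments at known
(optionally orthologous) positions, labelled proteomes, and error-free
RNA-seq reads with known counts — all byte-reproducible from a seed.

## Worked example

```
$ bsfvirome report --out out/
EVE records: 27; loci: 9; span 148-3750 nt
```

`report` summarises the packaged curated tables: 27 EVE records across three
assemblies (five *Partitiviridae*, spans from 148 to 3750 nt, nine distinct
orthologous loci, spread over four chromosomes of the chromosome-level
assembly), and writes the TPM ratio table — e.g. pol/Actin-5C of 0.009 in
the first larval sample and gag/Actin-5C of 0.434 in the egg-mass sample,
i.e. viral RNA is a tiny fraction of actin expression in larvae but
comparable to it in eggs.

A fully synthetic end-to-end run:

```
$ bsfvirome simulate --out sim/ --seed 11
wrote synthetic world (24 planted EVEs) to sim
$ bsfvirome find-eves --assembly sim/A1.fasta --assembly sim/A2.fasta \
    --assembly sim/A3.fasta --viral-proteome sim/viral_proteome.fasta \
    --taxonomy sim/taxonomy.tsv --host-proteome sim/host_proteome.fasta \
    --out eves/
called 22 EVEs across 3 assemblies
```

The 24 planted inserts include one contamination case (an EVE spanning its
whole contig) and one host-protein decoy; the pipeline calls exactly the 22
genuine ones. `assign-loci` then groups them into nine loci anchored on the
reference assembly.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes everything from scratch: the fixture-table summaries and ratios
above, plus a seeded synthetic EVE-discovery run scored against its planted
truth (recovery, false positives, and the locus presence matrix are logged
to stderr). The JSON written to `--out` holds the per-target results.

## Layout

| module | role |
| --- | --- |
| `io_formats` | FASTA/FASTQ/tabular-hit I/O, coordinate-string dialect |
| `synthetic_data` | ground-truth generators for every pipeline input |
| `homology_search` | six-frame translated search + host-protein screen |
| `eve_caller` | hit merging, contamination filter, EVE calls, summaries |
| `orthology_mapper` | flank-based locus assignment across assemblies |
| `virus_annotator` | ORF/GAG-POL annotation, triage, alignment prep |
| `quantifier` | read counting, TPM, housekeeping ratios |
| `fixtures` | packaged curated summary tables (validated on load) |
| `cli` | `bsfvirome` command-line entry point |
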