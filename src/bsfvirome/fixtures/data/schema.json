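{
  "table1": {
    "description": "Curated EVE summary records across three host genome assemblies",
    "columns": ["family", "eve_name", "locus_label", "bga", "best_hit", "aa_pct", "protein_class", "coordinates"],
    "n_records": 27,
    "locus_labels": ["PT", "PR1", "PR2", "PR3", "Rh", "T1", "T2", "T3", "Xi", "np"],
    "coordinate_dialect": "SEQID:START-END with span = END - START"
  },
  "table2": {
    "description": "RNA-seq datasets with near-complete virus contigs (>5 kb)",
    "columns": ["contig_name", "sra_id", "bioproject", "sample"],
    "n_records": 5
  },
  "table3": {
    "description": "Per-sample TPM over the pol/gag viral CDS features and the Actin-5C housekeeping gene",
    "features": ["pol", "gag", "Actin-5C"],
    "samples": ["contig 1", "contig 2", "contig 3", "contig 4", "contig 5"],
    "housekeeping": "Actin-5C",
    "larval_samples": ["contig 1", "contig 2", "contig 3", "contig 4"],
    "egg_samples": ["contig 5"],
    "column_sum": 1000000
  }
}
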