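contig_name	sra_id	bioproject	sample
contig 1	SRR14339788	PRJNA573413	Midgut of four-day-old larvae reared on food waste
contig 2	SRR10158821.1	PRJNA573413	Midgut of four-day-old larvae reared on cow manure
contig 3	SRR14339795	PRJNA573413	Midgut of eight-day-old larvae reared on cow manure
contig 4	ERR1801992.1	PRJEB19091	Five individual larvae
contig 5	SRR8242288	PRJNA506627	Egg Mass
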