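feature	contig 1	contig 2	contig 3	contig 4	contig 5
pol	9343	6192	3416	3590	204488
gag	6848	3473	2302	2494	240733
Actin-5C	983809	990335	994282	993916	554779
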