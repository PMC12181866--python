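rank	canonical_term
1	transcript_ablation
2	splice_acceptor_variant
3	splice_donor_variant
4	stop_gained
5	frameshift_variant
6	stop_lost
7	start_lost
8	transcript_amplification
9	feature_elongation
10	feature_truncation
11	inframe_insertion
12	inframe_deletion
13	missense_variant
14	protein_altering_variant
15	splice_donor_5th_base_variant
16	splice_region_variant
17	splice_donor_region_variant
18	splice_polypyrimidine_tract_variant
19	incomplete_terminal_codon_variant
20	start_retained_variant
21	stop_retained_variant
22	synonymous_variant
23	coding_sequence_variant
24	mature_miRNA_variant
25	5_prime_UTR_variant
26	3_prime_UTR_variant
27	non_coding_transcript_exon_variant
28	intron_variant
29	NMD_transcript_variant
30	non_coding_transcript_variant
31	coding_transcript_variant
32	upstream_gene_variant
33	downstream_gene_variant
34	TFBS_ablation
35	TFBS_amplification
36	TF_binding_site_variant
37	regulatory_region_ablation
38	regulatory_region_amplification
39	regulatory_region_variant
40	intergenic_variant
41	sequence_variant
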