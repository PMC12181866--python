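tool	raw_term	canonical_term
annovar	stopgain	stop_gained
annovar	stoploss	stop_lost
annovar	startloss	start_lost
annovar	startgain	5_prime_UTR_variant
annovar	frameshift insertion	frameshift_variant
annovar	frameshift deletion	frameshift_variant
annovar	frameshift substitution	frameshift_variant
annovar	frameshift block substitution	frameshift_variant
annovar	nonframeshift insertion	inframe_insertion
annovar	nonframeshift deletion	inframe_deletion
annovar	nonframeshift substitution	protein_altering_variant
annovar	nonframeshift block substitution	protein_altering_variant
annovar	nonsynonymous SNV	missense_variant
annovar	synonymous SNV	synonymous_variant
annovar	splicing	splice_region_variant
annovar	exonic	coding_sequence_variant
annovar	intronic	intron_variant
annovar	intergenic	intergenic_variant
annovar	upstream	upstream_gene_variant
annovar	downstream	downstream_gene_variant
annovar	UTR5	5_prime_UTR_variant
annovar	UTR3	3_prime_UTR_variant
annovar	ncRNA_exonic	non_coding_transcript_exon_variant
annovar	ncRNA_intronic	intron_variant
annovar	ncRNA_splicing	splice_region_variant
annovar	ncRNA_UTR5	non_coding_transcript_exon_variant
annovar	ncRNA_UTR3	non_coding_transcript_exon_variant
snpeff	initiator_codon_variant	start_lost
snpeff	disruptive_inframe_insertion	inframe_insertion
snpeff	disruptive_inframe_deletion	inframe_deletion
snpeff	conservative_inframe_insertion	inframe_insertion
snpeff	conservative_inframe_deletion	inframe_deletion
snpeff	5_prime_UTR_premature_start_codon_gain_variant	5_prime_UTR_variant
snpeff	non_coding_exon_variant	non_coding_transcript_exon_variant
snpeff	nc_transcript_variant	non_coding_transcript_variant
snpeff	start_retained	start_retained_variant
snpeff	stop_retained	stop_retained_variant
snpeff	exon_loss_variant	transcript_ablation
snpeff	gene_fusion	feature_truncation
vep	protein_altering_variant	protein_altering_variant
clinvar	nonsense	stop_gained
clinvar	genic_upstream_transcript_variant	upstream_gene_variant
clinvar	genic_downstream_transcript_variant	downstream_gene_variant
clinvar	no_sequence_alteration	sequence_variant
clinvar	initiatior_codon_variant	start_lost
clinvar	initiator_codon_variant	start_lost
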