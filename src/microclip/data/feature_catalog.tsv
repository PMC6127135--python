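name	nodes	family
t2c_ratio_cluster	1,7	clip
t2c_ratio_mre	1,7	clip
aggregate_sub_ratio	1,7	clip
sub_rel_position	1,7	clip
t2c_dist_mre_start	1,7	clip
sub_dist_mre_start	1,7	clip
cluster_rpkm	1,7	clip
mre_rpkm	1,7	clip
mre_cluster_coverage_ratio	1,7	clip
freq_A_mre	1,8	mononucleotide
freq_C_mre	1,8	mononucleotide
freq_G_mre	1,8	mononucleotide
freq_T_mre	1,8	mononucleotide
freq_A_upflank	1,8	mononucleotide
freq_C_upflank	1,8	mononucleotide
freq_G_upflank	1,8	mononucleotide
freq_T_upflank	1,8	mononucleotide
freq_A_downflank	1,8	mononucleotide
freq_C_downflank	1,8	mononucleotide
freq_G_downflank	1,8	mononucleotide
freq_T_downflank	1,8	mononucleotide
freq_AA_mre	1,8	dinucleotide
freq_AC_mre	1,8	dinucleotide
freq_AG_mre	1,8	dinucleotide
freq_AT_mre	1,8	dinucleotide
freq_CA_mre	1,8	dinucleotide
freq_CC_mre	1,8	dinucleotide
freq_CG_mre	1,8	dinucleotide
freq_CT_mre	1,8	dinucleotide
freq_GA_mre	1,8	dinucleotide
freq_GC_mre	1,8	dinucleotide
freq_GG_mre	1,8	dinucleotide
freq_GT_mre	1,8	dinucleotide
freq_TA_mre	1,8	dinucleotide
freq_TC_mre	1,8	dinucleotide
freq_TG_mre	1,8	dinucleotide
freq_TT_mre	1,8	dinucleotide
dust_mre	1,8	complexity
shannon_mre	1,8	complexity
dust_upflank	1,8	complexity
shannon_upflank	1,8	complexity
dust_downflank	1,8	complexity
shannon_downflank	1,8	complexity
gc_skew_mre	1,8	skew
at_skew_mre	1,8	skew
purine_skew_mre	1,8	skew
keto_skew_mre	1,8	skew
codon_usage_bias_mre	1,8	codon
nn_dh_mre	1,8	thermo
nn_ds_mre	1,8	thermo
nn_dg_mre	1,8	thermo
tm_mre	1,8	thermo
cons_mre	1,9	conservation
cons_upflank	1,9	conservation
cons_downflank	1,9	conservation
cons_seed_bind	1,9	conservation
bv_mirna_01	2	binding_vector
bv_mirna_02	2	binding_vector
bv_mirna_03	2	binding_vector
bv_mirna_04	2	binding_vector
bv_mirna_05	2	binding_vector
bv_mirna_06	2	binding_vector
bv_mirna_07	2	binding_vector
bv_mirna_08	2	binding_vector
bv_mirna_09	2	binding_vector
bv_mirna_10	2	binding_vector
bv_mirna_11	2	binding_vector
bv_mirna_12	2	binding_vector
bv_mirna_13	2	binding_vector
bv_mirna_14	2	binding_vector
bv_mirna_15	2	binding_vector
bv_mirna_16	2	binding_vector
bv_mirna_17	2	binding_vector
bv_mirna_18	2	binding_vector
bv_mirna_19	2	binding_vector
bv_mirna_20	2	binding_vector
bv_mirna_21	2	binding_vector
bv_mirna_22	2	binding_vector
bv_mirna_23	2	binding_vector
bv_mirna_24	2	binding_vector
bv_mirna_25	2	binding_vector
seed_matches	3,9	domain_matches
central_matches	3,9	domain_matches
supplementary_matches	3,9	domain_matches
tail_matches	3,9	domain_matches
seed_run	3,9	domain_matches
central_run	3,9	domain_matches
supplementary_run	3,9	domain_matches
tail_run	3,9	domain_matches
total_matches	3,9	domain_matches
longest_run	3,9	domain_matches
total_mismatches	3,9	domain_matches
site_matches	3,9	domain_matches
site_longest_run	3,9	domain_matches
duplex_energy	4,7	duplex
seed_duplex_energy	4,7	duplex
bulge_count	4,7	duplex
longest_bulge	4,7	duplex
internal_loop_count	4,7	duplex
longest_internal_loop	4,7	duplex
gu_wobble_count	4,7	duplex
dangling_end_len	4,7	duplex
au_pairs_seed	4,7	duplex
au_pairs_supplementary	4,7	duplex
au_pairs_total	4,7	duplex
au_content_upflank	4,7	duplex
au_content_downflank	4,7	duplex
comp_A_site_paired	5,8	pairing_composition
comp_C_site_paired	5,8	pairing_composition
comp_G_site_paired	5,8	pairing_composition
comp_T_site_paired	5,8	pairing_composition
comp_A_site_unpaired	5,8	pairing_composition
comp_C_site_unpaired	5,8	pairing_composition
comp_G_site_unpaired	5,8	pairing_composition
comp_T_site_unpaired	5,8	pairing_composition
comp_A_mirna_paired	5,8	pairing_composition
comp_C_mirna_paired	5,8	pairing_composition
comp_G_mirna_paired	5,8	pairing_composition
comp_T_mirna_paired	5,8	pairing_composition
comp_A_mirna_unpaired	5,8	pairing_composition
comp_C_mirna_unpaired	5,8	pairing_composition
comp_G_mirna_unpaired	5,8	pairing_composition
comp_T_mirna_unpaired	5,8	pairing_composition
mre_cluster_overlap	6,9	mre_general
mre_rel_location	6,9	mre_general
binding_type_code	6,9	mre_general
paired_gc_skew	6,9	mre_general
paired_at_skew	6,9	mre_general
paired_purine_skew	6,9	mre_general
mirna_paired_ratio	6,9	mre_general
site_paired_ratio	6,9	mre_general
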