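# fflnet 0.1.0 stage=summary config=b1d484598b83 seed=7
n_ffls_total	550
n_ffls_TF_FFL	243
n_ffls_MIRNA_FFL	280
n_ffls_FB_FFL	27
n_dysregulated_total	39
n_dysregulated_TF_FFL	13
n_dysregulated_MIRNA_FFL	20
n_dysregulated_FB_FFL	6
n_hub_ffls	0
cancer_gene_fisher_p	6.02083e-06
cancer_gene_odds_ratio	7.48884
n_ffls_system1	8
n_ffls_system2	7
n_ffls_system3	9
n_ffls_system4	6
n_ffls_system5	5
n_specific	16
n_general	3
n_assigned	24
pattern_CAN_A	consistent
pattern_CAN_B	consistent
pattern_CAN_C	reverse
pattern_CAN_D	reverse
pattern_CAN_E	reverse
pattern_CAN_F	
top_mirna_inhibitor	DRUG001
top_reversal_drug	DRUG001
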