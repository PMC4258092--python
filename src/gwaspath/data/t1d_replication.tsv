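# Replication P-values for the 22 candidate SNPs followed up in additional
# type 1 diabetes cohorts (inverse-variance meta-analysis of the replication
# samples; the SNP shared by CDC34 and MADCAM1 appears once).
# The entries for rs1296023 and rs11170466 are upper-bound stand-ins (0.049):
# the source table reports them only as below the 0.05 threshold, which is all
# the replication count and its binomial tail depend on.
snp_id	gene_ids	replication_p
rs6427658	IL6R	0.3260
rs10912276	FASLG	0.0290
rs2182419	PTPRC	0.9593
rs2450855	RAF1	0.7642
rs4502701	TRPC3	0.3697
rs1445898	IL7R	0.0146
rs4246045	DCTN4	0.8456
rs2048698	IRF4	0.0296
rs11964650	FYN	0.0183
rs1296023	CTSB	0.049
rs1557150	ITGB1	0.0119
rs722988	NRP1	0.0013
rs2293576	PSMC3	0.7537
rs694739	BAD	0.0031
rs11216829	AMICA1	0.5807
rs11170466	ITGB7	0.049
rs1360485	HMGB1	0.3819
rs149310	SOCS1	0.0064
rs16956936	TP53	0.0834
rs9906760	UBE2G1	0.0047
rs17759555	MAP3K14	0.0047
rs12982646	CDC34,MADCAM1	0.2323
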