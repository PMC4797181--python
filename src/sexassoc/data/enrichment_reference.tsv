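# Reconstructed per-trait 2x2 tables of significant (P < 0.05) SNP-trait
# associations by direction and sex, from the published bar-chart summary
# of the Spanish melanoma case-control study. The integer counts are a
# reconstruction: they were recovered from the printed percentages
# (e.g. eye colour 72.72% vs 40.74% protective) together with the printed
# pooled protective totals (107 female vs 75 male) and validated by
# reproducing all seven printed contingency-test P values. prot = OR < 1
# (dark pigmentation / good sun tolerance), risk = OR > 1.
trait	prot_f	risk_f	prot_m	risk_m
eye	16	6	11	16
hair	22	6	14	15
skin	16	8	13	18
naevi	17	9	11	19
sunburn	22	14	13	23
lentigines	14	11	13	17
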