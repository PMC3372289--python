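# Default single-copy-gene model list: 53 universal prokaryotic families,
# dominated by the translation machinery (ribosomal proteins, tRNA
# synthetase domains) whose presence is genome-size independent. The
# per-sample mean count over these models estimates genome equivalents.
# Editable curated default; model_length in residues.
model_name	model_length
Ribosomal_S2	182
Ribosomal_S3_C	84
Ribosomal_S4	95
Ribosomal_S5	62
Ribosomal_S7	148
Ribosomal_S8	128
Ribosomal_S9	120
Ribosomal_S10	97
Ribosomal_S11	112
Ribosomal_S12	123
Ribosomal_S13	111
Ribosomal_S15	83
Ribosomal_S16	73
Ribosomal_S17	66
Ribosomal_S19	78
Ribosomal_L1	226
Ribosomal_L2	85
Ribosomal_L3	197
Ribosomal_L4	188
Ribosomal_L5	54
Ribosomal_L6	82
Ribosomal_L10	99
Ribosomal_L11	68
Ribosomal_L13	139
Ribosomal_L14	121
Ribosomal_L16	126
Ribosomal_L18p	111
Ribosomal_L22	103
Ribosomal_L23	68
Ribosomal_L24	56
Ribosomal_L29	60
tRNA-synt_1	316
tRNA-synt_1c	321
tRNA-synt_1d	383
tRNA-synt_2	285
tRNA-synt_2b	227
tRNA-synt_2d	281
GTP_EFTU	188
IF-2	98
IF3_C	84
SmpB	142
RecA	322
SecY	415
SRP54	196
RBFA	105
RimM	83
TruB_N	140
PNPase	83
RNA_pol_A_bac	160
RNA_pol_Rpb2_6	72
GrpE	165
Trigger_N	110
SecE	58
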