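# Default transcription-factor model list: 65 usable prokaryotic regulator
# Pfam families (39 DNA-binding-domain models + 26 associated effector /
# receiver / substrate-binding domains). CtsR (PF05848) is omitted as a
# model without usable hits in surface-ocean metagenomes. This is an
# editable curated default; model_length in residues is used when emitting
# synthetic domtblout records.
model_name	category	model_length
HTH_1	DBD	61
HTH_3	DBD	55
HTH_5	DBD	44
HTH_6	DBD	81
HTH_8	DBD	90
HTH_10	DBD	48
HTH_11	DBD	55
HTH_AraC	DBD	42
HTH_DeoR	DBD	56
GntR	DBD	64
LacI	DBD	46
TetR_N	DBD	47
Trp_repressor	DBD	91
LytTR	DBD	97
MarR	DBD	58
ArsR	DBD	75
Crp	DBD	32
Fur	DBD	117
MerR	DBD	37
PadR	DBD	52
Rrf2	DBD	118
IclR	DBD	54
Penicillinase_R	DBD	113
GerE	DBD	58
LexA_DNA_bind	DBD	65
Arg_repressor	DBD	72
Fe_dep_repress	DBD	57
ROK	DBD	282
Mga	DBD	88
MetJ	DBD	93
TrmB	DBD	92
CopG	DBD	43
RHH_1	DBD	38
HrcA	DBD	318
PaaX	DBD	179
KorB	DBD	61
WhiA	DBD	77
Sigma70_r4	DBD	52
Sigma70_r2	DBD	68
Response_reg	non-DBD	112
Peptidase_S24	non-DBD	90
Pro_dh	non-DBD	270
Aldedh	non-DBD	462
Sugar_bind	non-DBD	116
UTRA	non-DBD	134
TOBE	non-DBD	62
LysR_substrate	non-DBD	207
PAS	non-DBD	113
PAS_3	non-DBD	81
PAS_4	non-DBD	110
GAF	non-DBD	144
CBS	non-DBD	57
ACT	non-DBD	72
SIS	non-DBD	133
Autoind_bind	non-DBD	159
FCD	non-DBD	151
PRD	non-DBD	98
Cupin_2	non-DBD	67
Fe_dep_repr_C	non-DBD	77
TrkA_N	non-DBD	115
ANTAR	non-DBD	59
AraC_binding	non-DBD	111
Arg_repressor_C	non-DBD	69
PTS_EIIA_2	non-DBD	141
Peripla_BP_1	non-DBD	333
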