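gene	signed_fc
CYP2E1	-2.7887
ACADVL	-2.64
HSD17B8	-2.428
ADHFE1	-2.3643
ACSBG1	-2.3277
HSD17B4	-2.3023
ACAA1	-2.2625
ACOX1	-2.175
ACSL1	-2.174
ACADM	-2.1376
CPT2	-2.1299
HSD17B10	-2.1022
EHHADH	-2.0911
HADHA	-1.9032
HADHB	-1.8385
ECHS1	-1.8378
SLC27A4	-1.7369
ACSL6	-1.736
ACADL	-1.6304
ACSL5	-1.6065
SLC27A1	-1.572
ACOX3	1.54147
ACSBG2	1.60749
ALDH7A1	1.78087
ALDH3A2	1.8053
ACSL4	3.1309
CPT1A	NA
ALDH2	NA
SLC27A6	NA
SDS	NA
ACAT1	NA
ADH6A	NA
ADH5	NA
DCXR	NA
ALDH1A2	NA
ALDH1A1	NA
SLC27A5	NA
IVD	NA
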