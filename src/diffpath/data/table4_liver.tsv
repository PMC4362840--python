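gene	signed_fc
SDS	-3.28557
ACSBG1	-1.72659
ALDH3A2	1.55345
ACSBG2	1.74991
ALDH1A2	1.90081
ACSL6	2.4039
ACAA1	2.47745
ACSL4	2.94002
ACSL5	NA
SLC27A1	NA
SLC27A4	NA
ACAT1	NA
CPT1A	NA
CPT2	NA
ACOX1	NA
ACOX3	NA
ACADVL	NA
EHHADH	NA
ECHS1	NA
HADHA	NA
HADHB	NA
HSD17B10	NA
HSD17B4	NA
ADH6A	NA
ADH5	NA
ACADM	NA
ACADL	NA
ALDH2	NA
ALDH7A1	NA
DCXR	NA
ADHFE1	NA
ALDH1A1	NA
CYP2E1	NA
ACSL1	NA
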