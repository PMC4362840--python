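gene	signed_fc
ALDH1A1	-4.19187
HSD17B4	-3.58868
ACAA1	-3.11098
ACSL3	-2.40998
IVD	-2.25629
ACOX1	-2.14926
ACSL4	-2.12389
ACSL6	-2.10271
ECHS1	-2.02957
ALDH3A2	-1.97016
SLC27A4	-1.95574
ACAA2	-1.82191
ACAT1	-1.78422
ACADVL	-1.7823
CPT2	-1.73571
ALDH2	-1.73348
HSD17B10	-1.67733
ACSBG2	-1.60441
CYP2E1	-1.56151
HADHA	-1.54366
ADH5	-1.54339
ALDH1A2	1.72927
CPT1A	1.95779
DCXR	2.01625
ACOX3	2.02906
ADH6A	2.19604
ACSBG1	NA
ACSL5	NA
SLC27A1	NA
ACSL1	NA
EHHADH	NA
HADHB	NA
SDS	NA
ACADM	NA
ACADL	NA
ALDH7A1	NA
ADHFE1	NA
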