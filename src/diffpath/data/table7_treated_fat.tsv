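gene	signed_fc
ALDH1A2	-5.1818
ALDH1A1	-4.1157
SLC27A4	-3.8033
ALDH2	-3.7982
CPT1A	-3.6059
ACSL5	-3.0073
ACOX3	-2.7208
ALDH7A1	-2.5909
ALDH3A2	-2.3444
IVD	-2.2947
ACOX1	-2.0718
ADH5	-1.9237
CYP2E1	-1.7096
DCXR	-1.6946
ACSL1	-1.5251
ADHFE1	1.52237
HSD17B4	1.54675
SLC27A6	1.60681
ACAT1	1.89588
ACSBG2	1.89683
ADH6A	2.02657
ACAA1	2.02752
ACSL6	2.10495
SLC27A5	2.51732
SDS	2.65876
SLC27A1	NA
ACSL4	NA
CPT2	NA
ACADM	NA
ACADL	NA
HSD17B8	NA
ACADVL	NA
EHHADH	NA
ECHS1	NA
HADHA	NA
HADHB	NA
HSD17B10	NA
ACSBG1	NA
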