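gene	signed_fc
EHHADH	-7.26916
ALDH2	-6.37787
ALDH1A1	-5.94915
SLC27A5	-5.0653
ALDH7A1	-4.70793
ACADVL	-4.33359
ACOX1	-3.99613
SLC27A4	-3.15579
ACSL3	-2.98288
DCXR	-2.67591
ADHFE1	-2.67386
ACAT1	-2.6477
IVD	-2.5505
ACOX3	-2.51966
HSD17B4	-2.50286
CPT2	-2.42769
ACAA2	-2.32958
ACADL	-2.2378
ACSL4	-2.20483
ECHS1	-2.17225
HSD17B10	-2.08251
ADH5	-2.02934
ACAA1	NA
ACADM	NA
ACSBG1	NA
ACSBG2	NA
ACSL1	NA
ACSL5	NA
ACSL6	NA
ADH6A	NA
ALDH1A2	NA
ALDH3A2	NA
CPT1A	NA
SDS	NA
SLC27A1	NA
HSD17B8	NA
SLC27A6	NA
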