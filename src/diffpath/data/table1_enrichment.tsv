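pathway	mkr_vs_wt_fat	mkr_vs_wt_liver	mkr_vs_wt_muscle	prediabetic_mkr_vs_wt_liver	cl_treated_vs_vehicle_mkr_fat
Fatty acid biosynthesis	0.037	0.006	0.259	0.007	0.676
Fatty acid elongation	0.026	0.201	0.016	1.61E-05	0.731
Fatty acid degradation	1.79E-08	0.319	1.17E-05	3.31E-14	0.012
Synthesis and degradation of ketone bodies	0.381	0.422	0.103	5.27E-05	0.183
Steroid biosynthesis	0.060	0.081	0.002	9.23E-08	0.166
Primary bile acid biosynthesis	0.081	0.036	0.027	0.001	0.073
Steroid hormone biosynthesis	0.341	0.0008	0.097	0.001	0.114
Glycerolipid metabolism	8.45E-06	2.90E-05	1.98E-08	2.84E-08	7.49E-06
Fat digestion and absorption	0.181	0.244	5.40E-03	2.57E-05	6.86E-03
Glycerophospholipid metabolism	3.27E-12	9.99E-06	5.75E-08	2.22E-08	7.57E-09
Ether lipid metabolism	0.0004	0.002	0.002	0.0006	5.61E-07
Sphingolipid metabolism	0.079	0.0003	0.007	0.002	0.0003
Arachidonic acid metabolism	0.014	0.001	0.002	0.007	0.002
Linoleic acid metabolism	0.054	0.248	0.025	0.065	0.010
alpha-Linolenic acid metabolism	0.012	0.050	0.055	0.015	0.001
Biosynthesis of unsaturated fatty acids	0.085	0.006	0.055	3.35E-06	0.153
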