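population	mean_het_wgs	mean_het_array	concordant_pct	discordant_pct	het_array_hom_wgs_pct	hom_array_het_wgs_pct	roh_error_pct
FIN	2432921.7	398280.1	99.6929	0.3071	0.0402	0.2669	0.227
GBR	2463526.4	405223.1	99.6898	0.3102	0.0430	0.2672	0.224
IBS	2440125.2	399870.1	99.6547	0.3453	0.0412	0.3041	0.263
TSI	2445524.4	401124.4	99.6015	0.3985	0.0424	0.3562	0.314
CEU	2479523.5	417837.2	99.6365	0.3635	0.0402	0.3232	0.283
ACB	3283726.5	454173.7	99.6723	0.3277	0.0403	0.2874	0.247
ASW	3262716.1	462107.3	99.6526	0.3474	0.0448	0.3026	0.258
MXL	2524698.2	385362.1	99.7197	0.2803	0.0433	0.2370	0.194
CLM	2317649.7	377844.5	99.6716	0.3284	0.0460	0.2825	0.236
PEL	2100245.2	352485.3	99.6987	0.3013	0.0411	0.2601	0.219
PUR	2421174.0	381603.3	99.4125	0.5875	0.0448	0.5427	0.498
CDX	2313375.1	371361.9	99.7197	0.2803	0.0351	0.2452	0.210
CHB	2330226.6	377553.5	99.7197	0.2803	0.0366	0.2437	0.207
CHS	2317649.7	377844.5	99.6991	0.3009	0.0451	0.2558	0.211
JPT	2320417.1	375586.6	99.3659	0.6341	0.0354	0.5988	0.563
KHV	2350584.8	368521.5	99.8549	0.1451	0.0343	0.1109	0.077
YRI	2840113.4	463890.4	99.5746	0.4254	0.0383	0.3871	0.349
LWK	2840253.9	441435.7	99.5545	0.4455	0.0457	0.3998	0.354
ZUL	2840578.1	441536.6	98.7062	1.2938	0.6338	0.6600	0.026
BAG	2840658.6	441412.3	99.2791	0.7209	0.3157	0.4052	0.090
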