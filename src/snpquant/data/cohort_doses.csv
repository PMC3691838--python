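patient,gender,age,location,tumour_height_mm,dose_rate_gy_per_h,prescribed_gy,printed_adjacent_gy,printed_central_gy,printed_distal_gy
1,F,73,conjunctiva,0.5,4.30,278,1.22,0.33,0.04
2,M,65,conjunctiva,7.0,4.64,293,1.29,0.35,0.04
3,F,46,iris,2.0,5.00,550,2.42,0.66,0.08
4,F,50,iris,3.0,5.09,520,2.29,0.62,0.08
5,F,76,ciliary_body,3.6,4.94,527,2.31,0.63,0.08
6,F,40,conjunctiva,1.0,7.79,387,1.70,0.46,0.06
7,F,66,ciliary_body,5.0,9.54,1070,4.70,1.28,0.16
8,M,61,ciliary_body,1.2,7.17,500,2.20,0.60,0.08
9,M,73,conjunctiva,2.3,4.87,573,2.52,0.69,0.09
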