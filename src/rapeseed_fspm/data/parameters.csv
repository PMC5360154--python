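# Packaged parameter store for the young-rapeseed FSPM.
# table_id values:
#   leaf_extension  - per-rank blade-extension logistic (y_m cm, ts_0 degC d, b)
#   drymass_plant   - normalized whole-plant dry-mass double logistic (lower/upper branch + ts_tr)
#   drymass_rank    - normalized per-rank dry-mass logistic (single; H rank 3 double)
#   leaf_area       - whole-plant leaf-area logistic (LA_0 cm2, LA_max cm2, TS_m degC d, b per degC d)
#   wlr             - blade width/length ratio linear regression vs rank
#   pbr             - petiole/blade length ratio linear regression vs rank
#   lma             - leaf mass per area vs rank (exponential for H/M, constant kg m-2 for L)
# The H-treatment wlr intercept is transcribed as 0.8921; the source regression
# caption prints 0.08921, inconsistent with the reported H mean WLR of 0.849
# and with the M/L intercepts (0.8988, 0.8738) - treated as a dropped digit.
table_id,treatment,rank,parameter,value
leaf_extension,H,1,ts_0,152.66
leaf_extension,H,1,b,-0.09
leaf_extension,H,1,y_m,6.08
leaf_extension,H,2,ts_0,121.77
leaf_extension,H,2,b,-0.32
leaf_extension,H,2,y_m,7.99
leaf_extension,H,3,ts_0,246.15
leaf_extension,H,3,b,-1.10
leaf_extension,H,3,y_m,9.04
leaf_extension,H,4,ts_0,272.08
leaf_extension,H,4,b,-2.58
leaf_extension,H,4,y_m,8.73
leaf_extension,H,5,ts_0,344.69
leaf_extension,H,5,b,-9.88
leaf_extension,H,5,y_m,7.74
leaf_extension,M,1,ts_0,152.91
leaf_extension,M,1,b,-0.11
leaf_extension,M,1,y_m,6.95
leaf_extension,M,2,ts_0,41.74
leaf_extension,M,2,b,-1.05
leaf_extension,M,2,y_m,5.94
leaf_extension,M,3,ts_0,117.05
leaf_extension,M,3,b,-2.48
leaf_extension,M,3,y_m,7.36
leaf_extension,M,4,ts_0,192.93
leaf_extension,M,4,b,-4.05
leaf_extension,M,4,y_m,10.25
leaf_extension,M,5,ts_0,228.26
leaf_extension,M,5,b,-11.67
leaf_extension,M,5,y_m,9.27
leaf_extension,L,1,ts_0,215.52
leaf_extension,L,1,b,48.29
leaf_extension,L,1,y_m,3.08
leaf_extension,L,2,ts_0,167.12
leaf_extension,L,2,b,62.99
leaf_extension,L,2,y_m,3.69
leaf_extension,L,3,ts_0,12.16
leaf_extension,L,3,b,-4.02
leaf_extension,L,3,y_m,4.46
leaf_extension,L,4,ts_0,157.92
leaf_extension,L,4,b,11.01
leaf_extension,L,4,y_m,2.62
drymass_plant,H,,y_m_l,7.58
drymass_plant,H,,a_l,23.99
drymass_plant,H,,b_l,-16.06
drymass_plant,H,,c_l,6.15
drymass_plant,H,,ts_tr,0.38
drymass_plant,H,,y_m_h,1.00
drymass_plant,H,,a_h,-20.82
drymass_plant,H,,b_h,16.49
drymass_plant,H,,c_h,-2.07
drymass_plant,M,,y_m_l,1.10
drymass_plant,M,,a_l,0.05
drymass_plant,M,,b_l,-5.56
drymass_plant,M,,c_l,3.72
drymass_plant,M,,ts_tr,0.76
drymass_plant,M,,y_m_h,1.00
drymass_plant,M,,a_h,-106.04
drymass_plant,M,,b_h,175.29
drymass_plant,M,,c_h,-73.18
drymass_plant,L,,y_m_l,7.57
drymass_plant,L,,a_l,7.90
drymass_plant,L,,b_l,-8.23
drymass_plant,L,,c_l,4.70
drymass_plant,L,,ts_tr,0.53
drymass_plant,L,,y_m_h,1.00
drymass_plant,L,,a_h,-2.37
drymass_plant,L,,b_h,-3.99
drymass_plant,L,,c_h,2.88
drymass_rank,H,1,y_m,0.78
drymass_rank,H,1,a,45.49
drymass_rank,H,1,b,-48.05
drymass_rank,H,1,c,2.79
drymass_rank,H,2,y_m,0.93
drymass_rank,H,2,a,18.54
drymass_rank,H,2,b,-22.77
drymass_rank,H,2,c,2.72
drymass_rank,H,3,y_m,0.32
drymass_rank,H,3,a,-6.63
drymass_rank,H,3,b,-29.28
drymass_rank,H,3,c,5.66
drymass_rank,H,3,ts_tr,0.61
drymass_rank,H,3,y_m_h,15.31
drymass_rank,H,3,a_h,8.20
drymass_rank,H,3,b_h,-16.29
drymass_rank,H,3,c_h,10.63
drymass_rank,H,4,y_m,16.91
drymass_rank,H,4,a,9.16
drymass_rank,H,4,b,-16.26
drymass_rank,H,4,c,10.04
drymass_rank,H,5,y_m,0.96
drymass_rank,H,5,a,-16.11
drymass_rank,H,5,b,4.44
drymass_rank,H,5,c,4.82
drymass_rank,H,6,y_m,16.35
drymass_rank,H,6,a,5.46
drymass_rank,H,6,b,-14.69
drymass_rank,H,6,c,11.96
drymass_rank,M,1,y_m,0.86
drymass_rank,M,1,a,25.33
drymass_rank,M,1,b,-29.04
drymass_rank,M,1,c,2.23
drymass_rank,M,2,y_m,0.92
drymass_rank,M,2,a,0.21
drymass_rank,M,2,b,-7.69
drymass_rank,M,2,c,1.55
drymass_rank,M,3,y_m,0.83
drymass_rank,M,3,a,-21.35
drymass_rank,M,3,b,1.69
drymass_rank,M,3,c,2.90
drymass_rank,M,4,y_m,0.95
drymass_rank,M,4,a,7.03
drymass_rank,M,4,b,-17.70
drymass_rank,M,4,c,8.10
drymass_rank,M,5,y_m,1.02
drymass_rank,M,5,a,17.91
drymass_rank,M,5,b,-40.13
drymass_rank,M,5,c,19.44
drymass_rank,M,6,y_m,14.07
drymass_rank,M,6,a,15.86
drymass_rank,M,6,b,-35.45
drymass_rank,M,6,c,22.16
drymass_rank,L,1,y_m,0.90
drymass_rank,L,1,a,11.62
drymass_rank,L,1,b,-14.74
drymass_rank,L,1,c,1.82
drymass_rank,L,2,y_m,6.83
drymass_rank,L,2,a,4.14
drymass_rank,L,2,b,-5.85
drymass_rank,L,2,c,3.98
drymass_rank,L,3,y_m,38.46
drymass_rank,L,3,a,11.42
drymass_rank,L,3,b,-19.47
drymass_rank,L,3,c,12.18
leaf_area,H,,LA_0,17
leaf_area,H,,TS_m,380
leaf_area,H,,LA_max,119
leaf_area,H,,b,0.020
leaf_area,M,,LA_0,10
leaf_area,M,,TS_m,270
leaf_area,M,,LA_max,184
leaf_area,M,,b,0.019
leaf_area,L,,LA_0,5
leaf_area,L,,TS_m,135
leaf_area,L,,LA_max,33
leaf_area,L,,b,0.025
wlr,H,,slope,-0.0126
wlr,H,,intercept,0.8921
wlr,M,,slope,-0.0276
wlr,M,,intercept,0.8988
wlr,L,,slope,-0.0296
wlr,L,,intercept,0.8738
pbr,H,,slope,0.056
pbr,H,,intercept,0.9591
pbr,M,,slope,-0.0636
pbr,M,,intercept,1.0704
pbr,L,,slope,-0.1609
pbr,L,,intercept,1.1353
lma,H,,coeff,0.0133
lma,H,,exp,0.0585
lma,M,,coeff,0.0143
lma,M,,exp,0.0607
lma,L,,const,0.01639
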