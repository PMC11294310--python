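name,sharpness,rho50_lp_per_cm,rho10_lp_per_cm,max_slope_hu_per_mm,max_slope_sd_hu_per_mm,rel_diff_pct
Qr36,36,3.4,5.6,900,50,-47
Qr40,40,4.0,6.6,1000,50,-41
Qr44,44,4.6,7.7,1090,50,-35
Qr48,48,5.4,9.0,1200,50,-29
Qr56,56,7.4,10.8,1420,80,-16
Qr60,60,8.8,11.2,1550,140,-9
Qr64,64,10.1,11.2,1620,130,-4
Qr68,68,11.8,13.9,1660,110,-2
Qr72,72,14.1,17.3,1690,120,0
Qr76,76,15.8,18.7,1690,120,0
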