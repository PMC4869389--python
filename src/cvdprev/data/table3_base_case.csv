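model,risk_level,strategy_printed,cost_usd,incremental_cost_usd,effect_dalys_averted,incremental_effect,icer_usd_per_daly
cvd,low,No treatment,461,,0.00,,
cvd,low,ACEI_Diu,1005,544,0.41,0.41,1327
cvd,low,ACEI_Diu_Sta,1259,254,0.49,0.08,3175
cvd,moderate,No treatment,1516,,0.00,,
cvd,moderate,ACEI_Diu,1683,167,1.02,1.02,164
cvd,moderate,ACEI_Diu_Sta,1827,144,1.28,0.26,554
cvd,high,No treatment,1695,,0.00,,
cvd,high,ACEI_CCB_Diu,2240,545,1.56,1.56,349
cvd,high,ACEI_CCB_Diu_Sta,2404,164,1.83,0.27,607
cvd,very_high,No treatment,2028,,0.00,,
cvd,very_high,ACEI_CCB_Diu_ASA,3244,1216,2.44,2.44,498
cvd,very_high,ACEI_CCB_Diu_Sta_ASA,3433,189,2.73,0.29,652
cvd_with_diabetes,low,No treatment,964,,0.00,,
cvd_with_diabetes,low,Sulf_ACEI_CCB,1481,517,0.85,0.85,608
cvd_with_diabetes,low,Big_Sulf_ACEI_CCB,1778,297,1.16,0.31,958
cvd_with_diabetes,low,Big_Sulf_ACEI_CCB_Sta,2026,248,1.26,0.10,2480
cvd_with_diabetes,moderate,No treatment,1805,,0.00,,
cvd_with_diabetes,moderate,Sulf_ACEI_CCB,1966,161,1.40,1.40,115
cvd_with_diabetes,moderate,Big_Sulf_ACEI_CCB,2122,156,2.01,0.61,256
cvd_with_diabetes,moderate,Big_Sulf_ACEI_CCB_Sta,2311,189,2.21,0.20,945
cvd_with_diabetes,high,No treatment,1909,,0.00,,
cvd_with_diabetes,high,Big_Sulf_ACEI_CCB,2576,667,2.16,2.16,309
cvd_with_diabetes,high,Big_Sulf_ACEI_CCB_Sta,2768,192,2.37,0.21,914
cvd_with_diabetes,high,Big_Sulf_ACEI_ARB_CCB_Sta,3798,1030,2.47,0.10,10300
cvd_with_diabetes,very_high,No treatment,2514,,0.00,,
cvd_with_diabetes,very_high,Big_Sulf_ACEI_CCB_ASA,3696,1182,3.38,3.38,350
cvd_with_diabetes,very_high,Big_Sulf_ACEI_CCB_Sta_ASA,3893,197,3.66,0.28,704
cvd_with_diabetes,very_high,Big_Sulf_ACEI_ARB_CCB_Sta_ASA,4883,990,3.79,0.13,7615
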