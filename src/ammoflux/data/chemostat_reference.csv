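strain,pH_EC,mu_1ph,qS_mmolgh,qO2_mmolgh,qCO2_mmolgh,qEtOH_mmolgh,qN_mmolgh,Ncontent_mmolg,biomass_gL,cellvol_mLg,NHX_IC_mM,NHX_EC_mM,YXS_gGlc,CN_CmolNmol,qATP_mmolgh,qATPperN_molmol
IME169,5.0,0.053,3.862,1.643,7.028,4.601,0.251,4.70,7.00,2.59,1.74,0.008,0.077,92.3,7.72,30.8
IME169,6.0,0.052,3.398,1.468,6.157,4.438,0.223,4.30,7.45,2.43,3.16,0.011,0.085,91.4,7.23,32.4
IME169,7.0,0.051,2.953,1.273,5.218,3.608,0.208,4.06,7.73,2.62,3.33,0.013,0.096,104.1,6.03,28.9
IMZ351,5.0,0.047,3.485,1.390,6.620,4.735,0.190,4.00,6.44,2.01,10.5,6.99,0.081,110.1,7.38,38.9
IMZ351,6.0,0.047,3.074,1.223,5.825,4.404,0.183,3.91,7.37,2.00,10.9,2.61,0.085,100.8,6.73,36.7
IMZ351,7.0,0.048,2.826,1.239,5.081,3.639,0.187,3.88,7.73,2.31,7.48,0.57,0.095,90.7,5.99,32.0
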