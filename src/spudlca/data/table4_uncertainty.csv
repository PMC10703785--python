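scenario,duration_weeks,category,mean,sd,cv_pct,p5,p95
FR-ID,2,FPM,2.21E-03,1.33E-04,6.01,2.00E-03,2.45E-03
FR-ID,2,FRS,1.69E-01,9.94E-03,5.87,1.53E-01,1.87E-01
FR-ID,2,FEW,4.96E-02,3.06E-03,6.17,4.48E-02,5.49E-02
FR-ID,2,FET,6.56E-03,4.37E-04,6.66,5.87E-03,7.29E-03
FR-ID,2,GW,2.16E+00,1.38E-01,6.41,1.94E+00,2.39E+00
FR-ID,2,HCT,7.44E-02,4.73E-03,6.36,6.69E-02,8.23E-02
FR-ID,2,HNCT,4.85E-01,2.88E-02,5.94,4.39E-01,5.34E-01
FR-ID,2,IR,2.92E-02,1.90E-03,6.51,2.62E-02,3.24E-02
FR-ID,2,LU,1.79E+00,1.19E-01,6.64,1.60E+00,1.98E+00
FR-ID,2,ME,5.42E-02,3.38E-03,6.24,4.88E-02,6.00E-02
FR-ID,2,MET,1.36E-03,8.73E-05,6.44,1.22E-03,1.50E-03
FR-ID,2,MRS,3.43E-03,2.18E-04,6.37,3.09E-03,3.80E-03
FR-ID,2,OFHH,2.84E-03,1.71E-04,6.02,2.58E-03,3.14E-03
FR-ID,2,OFTE,3.15E-03,1.88E-04,5.97,2.85E-03,3.48E-03
FR-ID,2,SOD,4.88E-06,3.12E-07,6.38,4.39E-06,5.41E-06
FR-ID,2,TAD,3.17E-03,1.90E-04,6.00,2.87E-03,3.50E-03
FR-ID,2,TET,1.69E+00,1.04E-01,6.14,1.52E+00,1.87E+00
FR-ID,2,WC,6.37E-02,3.99E-03,6.26,5.73E-02,7.05E-02
FR-CP,5,FPM,4.51E-04,3.14E-05,6.97,4.02E-04,5.04E-04
FR-CP,5,FRS,3.07E-02,2.11E-03,6.89,2.74E-02,3.42E-02
FR-CP,5,FEW,1.31E-02,8.89E-04,6.76,1.17E-02,1.46E-02
FR-CP,5,FET,1.76E-03,1.25E-04,7.08,1.56E-03,1.97E-03
FR-CP,5,GW,5.38E-01,3.79E-02,7.04,4.77E-01,6.01E-01
FR-CP,5,HCT,1.86E-02,1.30E-03,6.98,1.65E-02,2.07E-02
FR-CP,5,HNCT,1.11E-01,7.54E-03,6.77,9.93E-02,1.24E-01
FR-CP,5,IR,7.91E-03,5.49E-04,6.94,7.04E-03,8.82E-03
FR-CP,5,LU,4.92E-01,3.44E-02,7.00,4.36E-01,5.49E-01
FR-CP,5,ME,1.37E-02,9.39E-04,6.85,1.22E-02,1.53E-02
FR-CP,5,MET,3.78E-04,2.58E-05,6.83,3.37E-04,4.21E-04
FR-CP,5,MRS,9.54E-04,6.48E-05,6.80,8.51E-04,1.06E-03
FR-CP,5,OFHH,7.32E-04,4.76E-05,6.50,6.56E-04,8.13E-04
FR-CP,5,OFTE,8.44E-04,5.36E-05,6.35,7.59E-04,9.35E-04
FR-CP,5,SOD,1.36E-06,9.18E-08,6.77,1.21E-06,1.51E-06
FR-CP,5,TAD,7.10E-04,4.83E-05,6.81,6.33E-04,7.91E-04
FR-CP,5,TET,4.23E-01,2.87E-02,6.79,3.77E-01,4.70E-01
FR-CP,5,WC,1.80E-02,1.24E-03,6.87,1.61E-02,2.01E-02
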