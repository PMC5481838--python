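# fBM MME moment ratio <rmax^4>/<rmax^2>^2, 2D, Monte Carlo
# paths=200000 steps=512 seed=20170620
alpha,mme_ratio
0.10,1.1111
0.15,1.1226
0.20,1.1359
0.25,1.1505
0.30,1.1664
0.35,1.1835
0.40,1.2018
0.45,1.2211
0.50,1.2415
0.55,1.2630
0.60,1.2854
0.65,1.3088
0.67,1.3183
0.70,1.3330
0.75,1.3580
0.80,1.3839
0.85,1.4105
0.90,1.4378
0.95,1.4657
1.00,1.4966
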