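predictor,D1,D2,D3,D4,F1,F2,F3,F4,F5,F6,F7
D1,1.000,1.142,1.048,1.000,1.085,1.269,1.192,1.293,1.169,1.105,1.258
D2,1.332,1.000,1.000,1.109,1.091,1.000,1.014,1.000,1.000,1.020,1.000
D3,1.000,1.000,1.000,1.225,1.048,1.198,1.363,1.151,1.041,1.000,0.992
D4,1.122,1.037,1.131,1.000,1.175,1.000,1.000,1.000,1.000,0.919,1.000
F1,1.000,1.000,1.000,0.990,1.000,1.000,0.976,0.972,1.000,1.028,1.000
F2,1.000,1.000,1.012,1.000,1.063,1.000,0.978,0.949,0.981,0.947,0.896
F3,1.000,1.000,1.000,1.068,1.000,1.000,1.000,1.000,1.000,0.956,0.960
F4,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,0.983,0.941
F5,1.000,1.000,1.000,0.978,1.000,1.000,1.000,1.000,1.000,1.005,0.942
F6,0.967,1.000,0.977,0.989,1.000,1.000,1.011,1.000,1.022,1.000,1.000
F7,1.000,1.000,1.000,0.981,0.929,0.944,0.928,0.920,0.943,0.979,1.000
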