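code,label,t1_mean,t1_sd,t2_mean,t2_sd
D1,Cognition,3.30,2.13,2.58,1.74
D2,Emotion,2.23,1.45,2.07,1.59
D3,Time awareness,1.41,0.82,0.73,0.75
D4,Stress and pain,1.98,1.18,1.19,1.23
F1,Triggers,14.67,6.66,13.13,5.76
F2,Severity,17.40,5.34,15.37,4.68
F3,Psychological distress,7.05,2.95,5.23,2.28
F4,Functioning impairment,13.58,4.53,8.93,5.41
F5,Insight,5.84,2.46,9.11,4.68
F6,Reassurance,8.58,3.20,7.24,3.07
F7,Coping strategies,17.31,7.20,15.53,9.18
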