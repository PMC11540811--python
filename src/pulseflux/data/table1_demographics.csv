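subject_id,sex,age,height,weight,bmi,systolic_bp,diastolic_bp,heart_rate
1,M,28,1.73,69.2,23.6,116,65,69
2,F,26,1.65,61.6,23.0,128,77,56
3,M,26,1.63,64.7,24.9,104,60,69
4,F,24,1.65,53.6,20.1,107,68,78
5,M,26,1.73,75.9,25.8,119,63,55
6,M,26,1.70,71.4,25.1,120,69,54
7,F,26,1.73,58.0,19.8,116,72,78
8,F,28,1.78,80.4,25.8,117,76,51
9,M,26,1.80,80.4,25.1,121,68,68
10,F,24,1.60,47.3,18.8,128,78,79
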