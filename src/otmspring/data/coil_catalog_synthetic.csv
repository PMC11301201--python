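model_label,rest_length_mm,stiffness_N_per_mm,activation_length_mm
9-L,9,0.098,29
9-L+,9,0.098,31
12-L,12,0.098,37
12-L+,12,0.098,39
15-L,15,0.098,45
15-L+,15,0.098,47
9-M,9,0.245,23
9-M+,9,0.245,35
12-M,12,0.245,28
12-M+,12,0.245,40
15-M,15,0.245,33
15-M+,15,0.245,45
9-H,9,0.49,19
9-H+,9,0.49,25
12-H,12,0.49,23
15-H,15,0.49,27
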