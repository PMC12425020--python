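# PSTAR-style excerpt: protons in liquid water
# kinetic energy (MeV)   total mass stopping power (MeV cm^2/g)
1.0     260.8
2.0     159.1
3.0     117.7
5.0     79.11
10.0    45.67
15.0    33.33
20.0    26.07
25.0    21.49
30.0    18.76
40.0    14.88
50.0    12.45
60.0    10.80
70.0    9.559
80.0    8.625
100.0   7.289
150.0   5.445
200.0   4.492
250.0   3.911
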