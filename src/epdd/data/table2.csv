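energy_mev,N,n,mu_per_mm
6,3.1,90,0.001
9,6.2,210,0.0007
12,8.9,290,0.0005
15,12.3,400,0.0003
18,15.1,470,0.0002
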