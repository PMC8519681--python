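nominal_mev,e0_mev,n,N,slope_80_20,atan_slope_rad,mu_per_mm,ln_mu,seq_mm,seq_sqrt_mm
6,5.41,90,3.1,-8.6593,-1.45582,0.001,-6.9077,38.13,36.75
9,8.66,210,6.2,-5.7176,-1.39765,0.0007,-7.2644,49.17,46.5
12,11.27,290,8.9,-4.5559,-1.35473,0.0005,-7.6009,53.98,53.04
15,14.04,400,12.3,-3.3749,-1.28273,0.0003,-8.1117,59.33,59.2
18,17.03,470,15.1,-2.6474,-1.20964,0.0002,-8.5171,62.1,65.2
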