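nominal_mev,e0_mev,rmax_mm,dmax_mm,r90_mm,r50_mm,rp_mm,xray_pct
6,5.41,11.1,12.1,16.9,23.2,30.2,0.7
9,8.66,20.6,21.5,28.3,37.1,45.1,1.2
12,11.27,26.1,27.1,37.4,48.3,58.7,2.1
15,14.04,27.1,28.4,46.1,60.3,73.7,2.6
18,17.03,24.3,25.2,56.8,73.1,88.7,3.5
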