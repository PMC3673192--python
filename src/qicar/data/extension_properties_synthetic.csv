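ion,charge,AN,AR,r,rho,dE0,dIP,Z,AN_dIP,logKOH,MP,pKspCO3,sigma_p,Xm,Xm2r,Z_AR,Z2_r
Al,3,13,1.43,0.5,2.7,1.676,28.448,3,0.457,5.0,660.3,,0.224,1.61,1.2961,2.0979,18.0
Cr,6,24,1.28,0.44,7.19,1.33,90.635,6,0.2648,3.8,1907.0,,0.152,1.66,1.2125,4.6875,81.8182
V,5,23,1.34,0.54,6.11,1.0,65.282,5,0.3523,3.3,1910.0,,0.145,1.63,1.4347,3.7313,46.2963
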