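ion,charge,AN,AR,r,rho,dE0,dIP,Z,AN_dIP,logKOH,MP,pKspCO3,sigma_p,Xm,Xm2r,Z_AR,Z2_r
Li,1,3,1.52,0.6,0.534,3.04,5.392,1,0.5564,13.64,180.5,1.6,0.247,0.98,0.5762,0.6579,1.6667
Na,1,11,1.86,0.95,0.971,2.713,5.139,1,2.1405,14.18,97.8,,0.211,0.93,0.8217,0.5376,1.0526
K,1,19,2.27,1.33,0.862,2.931,4.341,1,4.3769,14.46,63.5,,0.232,0.82,0.8943,0.4405,0.7519
Cs,1,55,2.65,1.69,1.873,2.923,3.894,1,14.1243,14.92,28.5,,0.218,0.79,1.0547,0.3774,0.5917
Mg,2,12,1.6,0.65,1.738,2.372,15.035,2,0.7981,11.44,650.0,7.46,0.167,1.31,1.1155,1.25,6.1538
Ca,2,20,1.97,0.99,1.55,2.868,11.872,2,1.6846,12.85,842.0,8.35,0.181,1.0,0.99,1.0152,4.0404
Ba,2,56,2.17,1.35,3.594,2.912,10.004,2,5.5978,13.47,727.0,8.59,0.189,0.89,1.0693,0.9217,2.963
Mn,2,25,1.27,0.8,7.21,1.185,15.64,2,1.5985,10.59,1246.0,10.74,0.14,1.55,1.922,1.5748,5.0
Fe,2,26,1.26,0.76,7.874,0.447,16.188,2,1.6061,9.5,1538.0,10.5,0.135,1.83,2.5452,1.5873,5.2632
Co,2,27,1.25,0.74,8.9,0.28,17.084,2,1.5804,9.65,1495.0,9.98,0.13,1.88,2.6155,1.6,5.4054
Ni,2,28,1.24,0.72,8.908,0.257,18.169,2,1.5411,9.86,1455.0,6.87,0.126,1.91,2.6266,1.6129,5.5556
Ag,1,47,1.44,1.26,10.49,0.8,7.576,1,6.2038,12.0,961.8,11.09,0.074,1.93,4.6934,0.6944,0.7937
Cu,2,29,1.28,0.73,8.96,0.153,20.292,2,1.4291,8.0,1084.6,9.63,0.104,1.9,2.6353,1.5625,5.4795
Zn,2,30,1.34,0.74,7.134,0.762,17.964,2,1.67,8.96,419.5,10.84,0.115,1.65,2.0146,1.4925,5.4054
Cd,2,48,1.49,0.97,8.65,0.403,16.908,2,2.8389,10.08,321.1,12.1,0.081,1.69,2.7704,1.3423,4.1237
Hg,2,80,1.51,1.1,13.534,0.92,18.757,2,4.2651,3.4,-38.8,16.05,0.064,2.0,4.4,1.3245,3.6364
Pb,2,82,1.75,1.2,11.34,0.126,15.032,2,5.455,7.71,327.5,13.13,0.131,2.33,6.5147,1.1429,3.3333
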