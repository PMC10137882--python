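problem,LFD,HHO,SCA,EO,GSA,AOA,SAR,mSAR
F1,2.583E+10,4.733E+06,8.256E+09,2.307E+03,4.593E+09,3.398E+09,1.427E+06,3.942E+08
F2,4.647E+03,3.032E+03,4.892E+03,4.220E+03,4.685E+04,4.084E+03,3.236E+03,2.496E+03
F3,1.056E+03,9.340E+02,9.376E+02,7.478E+02,8.686E+02,8.779E+02,7.721E+02,1.077E+02
F4,1.636E+05,1.919E+03,3.277E+03,1.903E+03,6.343E+04,2.472E+03,1.906E+03,6.471E+03
F5,4.908E+06,6.073E+04,1.152E+06,1.454E+05,8.328E+07,1.525E+06,5.776E+05,1.447E+04
F6,1.667E+03,1.857E+03,2.049E+03,1.624E+03,1.624E+03,2.371E+03,2.049E+03,1.883E+02
F7,1.891E+06,3.251E+05,2.718E+05,9.194E+04,2.144E+06,1.745E+05,3.955E+03,1.056E+03
F8,5.111E+03,2.305E+03,3.165E+03,2.597E+03,4.968E+04,5.021E+03,2.311E+03,6.491E+03
F9,3.022E+03,3.258E+03,2.975E+03,2.827E+03,3.533E+03,2.985E+03,2.910E+03,1.004E+03
F10,4.505E+03,3.005E+03,3.220E+03,2.931E+04,3.310E+05,3.162E+03,2.913E+03,2.139E+03
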