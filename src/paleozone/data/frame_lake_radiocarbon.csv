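interval_cm,c14_age_bp,c14_err,f14c,f14c_err
0.5,405.0,20.0,0.9508,0.0024
1.0,591.0,19.0,0.929,0.0022
1.5,513.0,19.0,0.9382,0.0023
2.0,536.0,20.0,0.9354,0.0023
2.5,657.0,20.0,0.9215,0.0022
3.0,,,,
3.5,853.0,20.0,0.8993,0.0022
4.0,1044.0,21.0,0.8781,0.0022
4.5,1005.0,20.0,0.8824,0.0022
5.0,661.0,19.0,0.9211,0.0021
5.5,349.0,18.0,0.9574,0.0022
6.0,614.0,19.0,0.9264,0.0022
6.5,788.0,21.0,0.9065,0.0023
7.0,373.0,19.0,0.9546,0.0022
7.5,1070.0,18.0,0.8753,0.002
8.0,865.0,21.0,0.8979,0.0024
8.5,519.0,19.0,0.9375,0.0022
9.0,635.0,19.0,0.924,0.0022
9.5,955.0,21.0,0.8879,0.0023
10.0,749.0,19.0,0.911,0.0021
10.5,945.0,19.0,0.8891,0.0021
11.0,1012.0,23.0,0.8816,0.0025
11.5,872.0,22.0,0.8971,0.0025
12.0,1056.0,19.0,0.8768,0.0021
12.5,846.0,20.0,0.9001,0.0023
13.0,736.0,25.0,0.9125,0.0028
13.5,866.0,19.0,0.8978,0.0021
14.0,1123.0,64.0,0.8695,0.0069
14.5,1049.0,45.0,0.8776,0.0049
15.0,1233.0,20.0,0.8578,0.0021
19.5-20.5,7230.0,128.0,,
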