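energy_keV mu_over_rho_cm2_g mu_per_cm  # material=silver density_g_cm3=10.49
10.000 1.187000e+02 1.245163e+03
10.500 1.042623e+02 1.093712e+03
11.000 9.213498e+01 9.664959e+02
11.500 8.186710e+01 8.587858e+02
12.000 7.311029e+01 7.669270e+02
12.500 6.559241e+01 6.880643e+02
13.000 5.909859e+01 6.199442e+02
13.500 5.345762e+01 5.607705e+02
14.000 4.853185e+01 5.090991e+02
14.500 4.420968e+01 4.637595e+02
15.000 4.040000e+01 4.237960e+02
15.500 3.692687e+01 3.873628e+02
16.000 3.384878e+01 3.550737e+02
16.500 3.111049e+01 3.263491e+02
17.000 2.866583e+01 3.007046e+02
17.500 2.647601e+01 2.777334e+02
18.000 2.450828e+01 2.570919e+02
18.500 2.273485e+01 2.384886e+02
19.000 2.113204e+01 2.216751e+02
19.500 1.967957e+01 2.064387e+02
20.000 1.836000e+01 1.925964e+02
20.500 1.713613e+01 1.797580e+02
21.000 1.602045e+01 1.680545e+02
21.500 1.500115e+01 1.573621e+02
22.000 1.406796e+01 1.475729e+02
22.500 1.321187e+01 1.385925e+02
23.000 1.242501e+01 1.303384e+02
23.500 1.170046e+01 1.227378e+02
24.000 1.103210e+01 1.157268e+02
24.500 1.041455e+01 1.092487e+02
25.000 9.843018e+00 1.032533e+02
25.513 9.300000e+00 9.755700e+01
25.515 5.520000e+01 5.790480e+02
26.000 5.264111e+01 5.522052e+02
26.500 5.017323e+01 5.263172e+02
27.000 4.786400e+01 5.020933e+02
27.500 4.570054e+01 4.793987e+02
28.000 4.367125e+01 4.581115e+02
28.500 4.176564e+01 4.381216e+02
29.000 3.997419e+01 4.193292e+02
29.500 3.828825e+01 4.016438e+02
30.000 3.670000e+01 3.849830e+02
30.500 3.508873e+01 3.680808e+02
31.000 3.357271e+01 3.521777e+02
31.500 3.214489e+01 3.371999e+02
32.000 3.079887e+01 3.230802e+02
32.500 2.952880e+01 3.097571e+02
33.000 2.832930e+01 2.971744e+02
33.500 2.719548e+01 2.852806e+02
34.000 2.612285e+01 2.740287e+02
34.500 2.510727e+01 2.633752e+02
35.000 2.414494e+01 2.532804e+02
35.500 2.323238e+01 2.437076e+02
36.000 2.236635e+01 2.346230e+02
36.500 2.154389e+01 2.259954e+02
37.000 2.076226e+01 2.177961e+02
37.500 2.001891e+01 2.099984e+02
38.000 1.931150e+01 2.025777e+02
38.500 1.863786e+01 1.955111e+02
39.000 1.799595e+01 1.887775e+02
39.500 1.738391e+01 1.823572e+02
40.000 1.680000e+01 1.762320e+02
40.500 1.627519e+01 1.707267e+02
41.000 1.577291e+01 1.654579e+02
41.500 1.529195e+01 1.604126e+02
42.000 1.483115e+01 1.555788e+02
42.500 1.438945e+01 1.509453e+02
43.000 1.396584e+01 1.465016e+02
43.500 1.355938e+01 1.422379e+02
44.000 1.316920e+01 1.381449e+02
44.500 1.279446e+01 1.342139e+02
45.000 1.243440e+01 1.304369e+02
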