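energy_keV mu_over_rho_cm2_g mu_per_cm  # material=water density_g_cm3=1.0
10.000 5.329097e+00 5.329097e+00
10.500 4.631398e+00 4.631398e+00
11.000 4.052076e+00 4.052076e+00
11.500 3.566954e+00 3.566954e+00
12.000 3.157560e+00 3.157560e+00
12.500 2.809617e+00 2.809617e+00
13.000 2.511965e+00 2.511965e+00
13.500 2.255799e+00 2.255799e+00
14.000 2.034105e+00 2.034105e+00
14.500 1.841249e+00 1.841249e+00
15.000 1.672671e+00 1.672671e+00
15.500 1.538560e+00 1.538560e+00
16.000 1.419214e+00 1.419214e+00
16.500 1.312618e+00 1.312618e+00
17.000 1.217083e+00 1.217083e+00
17.500 1.131185e+00 1.131185e+00
18.000 1.053714e+00 1.053714e+00
18.500 9.836448e-01 9.836448e-01
19.000 9.200960e-01 9.200960e-01
19.500 8.623124e-01 8.623124e-01
20.000 8.096424e-01 8.096424e-01
20.500 7.717656e-01 7.717656e-01
21.000 7.365947e-01 7.365947e-01
21.500 7.038784e-01 7.038784e-01
22.000 6.733940e-01 6.733940e-01
22.500 6.449434e-01 6.449434e-01
23.000 6.183500e-01 6.183500e-01
23.500 5.934560e-01 5.934560e-01
24.000 5.701197e-01 5.701197e-01
24.500 5.482142e-01 5.482142e-01
25.000 5.276250e-01 5.276250e-01
25.500 5.082489e-01 5.082489e-01
26.000 4.899927e-01 4.899927e-01
26.500 4.727717e-01 4.727717e-01
27.000 4.565094e-01 4.565094e-01
27.500 4.411359e-01 4.411359e-01
28.000 4.265878e-01 4.265878e-01
28.500 4.128070e-01 4.128070e-01
29.000 3.997406e-01 3.997406e-01
29.500 3.873402e-01 3.873402e-01
30.000 3.755613e-01 3.755613e-01
30.500 3.682450e-01 3.682450e-01
31.000 3.612003e-01 3.612003e-01
31.500 3.544131e-01 3.544131e-01
32.000 3.478699e-01 3.478699e-01
32.500 3.415585e-01 3.415585e-01
33.000 3.354671e-01 3.354671e-01
33.500 3.295849e-01 3.295849e-01
34.000 3.239018e-01 3.239018e-01
34.500 3.184082e-01 3.184082e-01
35.000 3.130951e-01 3.130951e-01
35.500 3.079543e-01 3.079543e-01
36.000 3.029776e-01 3.029776e-01
36.500 2.981578e-01 2.981578e-01
37.000 2.934878e-01 2.934878e-01
37.500 2.889610e-01 2.889610e-01
38.000 2.845712e-01 2.845712e-01
38.500 2.803125e-01 2.803125e-01
39.000 2.761793e-01 2.761793e-01
39.500 2.721664e-01 2.721664e-01
40.000 2.682689e-01 2.682689e-01
40.500 2.657546e-01 2.657546e-01
41.000 2.632969e-01 2.632969e-01
41.500 2.608939e-01 2.608939e-01
42.000 2.585437e-01 2.585437e-01
42.500 2.562445e-01 2.562445e-01
43.000 2.539947e-01 2.539947e-01
43.500 2.517926e-01 2.517926e-01
44.000 2.496367e-01 2.496367e-01
44.500 2.475254e-01 2.475254e-01
45.000 2.454574e-01 2.454574e-01
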