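energy_keV mu_over_rho_cm2_g mu_per_cm  # material=glandular density_g_cm3=1.04
10.000 4.830075e+00 5.023278e+00
10.500 4.202860e+00 4.370974e+00
11.000 3.681475e+00 3.828734e+00
11.500 3.244395e+00 3.374171e+00
12.000 2.875158e+00 2.990164e+00
12.500 2.561025e+00 2.663466e+00
13.000 2.292034e+00 2.383715e+00
13.500 2.060314e+00 2.142727e+00
14.000 1.859592e+00 1.933976e+00
14.500 1.684824e+00 1.752217e+00
15.000 1.531923e+00 1.593200e+00
15.500 1.411059e+00 1.467501e+00
16.000 1.303389e+00 1.355524e+00
16.500 1.207122e+00 1.255407e+00
17.000 1.120755e+00 1.165585e+00
17.500 1.043020e+00 1.084741e+00
18.000 9.728412e-01 1.011755e+00
18.500 9.093020e-01 9.456741e-01
19.000 8.516177e-01 8.856824e-01
19.500 7.991142e-01 8.310787e-01
20.000 7.512093e-01 7.812577e-01
20.500 7.170365e-01 7.457179e-01
21.000 6.852884e-01 7.126999e-01
21.500 6.557398e-01 6.819694e-01
22.000 6.281911e-01 6.533187e-01
22.500 6.024649e-01 6.265635e-01
23.000 5.784031e-01 6.015392e-01
23.500 5.558643e-01 5.780989e-01
24.000 5.347219e-01 5.561108e-01
24.500 5.148622e-01 5.354567e-01
25.000 4.961830e-01 5.160303e-01
25.500 4.785917e-01 4.977354e-01
26.000 4.620051e-01 4.804854e-01
26.500 4.463476e-01 4.642015e-01
27.000 4.315505e-01 4.488126e-01
27.500 4.175516e-01 4.342536e-01
28.000 4.042939e-01 4.204657e-01
28.500 3.917258e-01 4.073948e-01
29.000 3.797997e-01 3.949917e-01
29.500 3.684725e-01 3.832114e-01
30.000 3.577043e-01 3.720125e-01
30.500 3.510318e-01 3.650731e-01
31.000 3.446079e-01 3.583922e-01
31.500 3.384194e-01 3.519562e-01
32.000 3.324539e-01 3.457521e-01
32.500 3.266999e-01 3.397679e-01
33.000 3.211467e-01 3.339925e-01
33.500 3.157841e-01 3.284155e-01
34.000 3.106029e-01 3.230271e-01
34.500 3.055942e-01 3.178180e-01
35.000 3.007498e-01 3.127798e-01
35.500 2.960619e-01 3.079044e-01
36.000 2.915233e-01 3.031842e-01
36.500 2.871271e-01 2.986122e-01
37.000 2.828669e-01 2.941816e-01
37.500 2.787367e-01 2.898861e-01
38.000 2.747307e-01 2.857199e-01
38.500 2.708436e-01 2.816773e-01
39.000 2.670703e-01 2.777531e-01
39.500 2.634060e-01 2.739422e-01
40.000 2.598461e-01 2.702399e-01
40.500 2.575288e-01 2.678300e-01
41.000 2.552644e-01 2.654750e-01
41.500 2.530509e-01 2.631730e-01
42.000 2.508866e-01 2.609221e-01
42.500 2.487698e-01 2.587206e-01
43.000 2.466989e-01 2.565668e-01
43.500 2.446723e-01 2.544591e-01
44.000 2.426885e-01 2.523960e-01
44.500 2.407462e-01 2.503760e-01
45.000 2.388440e-01 2.483977e-01
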