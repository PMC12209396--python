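energy_keV mu_over_rho_cm2_g mu_per_cm  # material=hydroxyapatite density_g_cm3=3.18
10.000 4.714125e+01 1.499092e+02
10.500 4.112508e+01 1.307777e+02
11.000 3.610548e+01 1.148154e+02
11.500 3.188267e+01 1.013869e+02
12.000 2.830332e+01 9.000454e+01
12.500 2.524835e+01 8.028974e+01
13.000 2.262433e+01 7.194536e+01
13.500 2.035723e+01 6.473598e+01
14.000 1.838784e+01 5.847332e+01
14.500 1.666843e+01 5.300560e+01
15.000 1.516021e+01 4.820947e+01
15.500 1.377898e+01 4.381716e+01
16.000 1.256171e+01 3.994622e+01
16.500 1.148467e+01 3.652125e+01
17.000 1.052817e+01 3.347957e+01
17.500 9.675734e+00 3.076883e+01
18.000 8.913537e+00 2.834505e+01
18.500 8.229899e+00 2.617108e+01
19.000 7.614914e+00 2.421543e+01
19.500 7.060142e+00 2.245125e+01
20.000 6.558361e+00 2.085559e+01
20.500 6.117643e+00 1.945410e+01
21.000 5.716237e+00 1.817764e+01
21.500 5.349818e+00 1.701242e+01
22.000 5.014620e+00 1.594649e+01
22.500 4.707357e+00 1.496940e+01
23.000 4.425152e+00 1.407198e+01
23.500 4.165477e+00 1.324622e+01
24.000 3.926107e+00 1.248502e+01
24.500 3.705077e+00 1.178214e+01
25.000 3.500646e+00 1.113205e+01
25.500 3.311271e+00 1.052984e+01
26.000 3.135576e+00 9.971131e+00
26.500 2.972336e+00 9.452029e+00
27.000 2.820457e+00 8.969052e+00
27.500 2.678956e+00 8.519080e+00
28.000 2.546953e+00 8.099312e+00
28.500 2.423658e+00 7.707231e+00
29.000 2.308355e+00 7.340569e+00
29.500 2.200401e+00 6.997276e+00
30.000 2.099214e+00 6.675502e+00
30.500 2.009446e+00 6.390037e+00
31.000 1.924961e+00 6.121377e+00
31.500 1.845371e+00 5.868279e+00
32.000 1.770318e+00 5.629611e+00
32.500 1.699477e+00 5.404338e+00
33.000 1.632552e+00 5.191516e+00
33.500 1.569270e+00 4.990279e+00
34.000 1.509381e+00 4.799833e+00
34.500 1.452657e+00 4.619450e+00
35.000 1.398887e+00 4.448460e+00
35.500 1.347876e+00 4.286247e+00
36.000 1.299448e+00 4.132244e+00
36.500 1.253436e+00 3.985926e+00
37.000 1.209688e+00 3.846809e+00
37.500 1.168065e+00 3.714448e+00
38.000 1.128436e+00 3.588427e+00
38.500 1.090680e+00 3.468363e+00
39.000 1.054686e+00 3.353901e+00
39.500 1.020349e+00 3.244710e+00
40.000 9.875734e-01 3.140484e+00
40.500 9.589238e-01 3.049378e+00
41.000 9.314843e-01 2.962120e+00
41.500 9.051895e-01 2.878503e+00
42.000 8.799782e-01 2.798331e+00
42.500 8.557933e-01 2.721423e+00
43.000 8.325811e-01 2.647608e+00
43.500 8.102914e-01 2.576727e+00
44.000 7.888773e-01 2.508630e+00
44.500 7.682945e-01 2.443176e+00
45.000 7.485016e-01 2.380235e+00
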