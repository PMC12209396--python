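energy_keV mu_over_rho_cm2_g mu_per_cm  # material=adipose density_g_cm3=0.95
10.000 3.269899e+00 3.106404e+00
10.500 2.858608e+00 2.715677e+00
11.000 2.515438e+00 2.389666e+00
11.500 2.226724e+00 2.115387e+00
12.000 1.981981e+00 1.882882e+00
12.500 1.773071e+00 1.684418e+00
13.000 1.593608e+00 1.513927e+00
13.500 1.438531e+00 1.366604e+00
14.000 1.303795e+00 1.238606e+00
14.500 1.186140e+00 1.126833e+00
15.000 1.082915e+00 1.028770e+00
15.500 1.004758e+00 9.545203e-01
16.000 9.347392e-01 8.880022e-01
16.500 8.717899e-01 8.282004e-01
17.000 8.150092e-01 7.742588e-01
17.500 7.636332e-01 7.254516e-01
18.000 7.170112e-01 6.811606e-01
18.500 6.745861e-01 6.408568e-01
19.000 6.358792e-01 6.040852e-01
19.500 6.004770e-01 5.704532e-01
20.000 5.680214e-01 5.396203e-01
20.500 5.461711e-01 5.188625e-01
21.000 5.257601e-01 4.994721e-01
21.500 5.066606e-01 4.813275e-01
22.000 4.887590e-01 4.643210e-01
22.500 4.719539e-01 4.483562e-01
23.000 4.561545e-01 4.333468e-01
23.500 4.412795e-01 4.192155e-01
24.000 4.272557e-01 4.058929e-01
24.500 4.140170e-01 3.933161e-01
25.000 4.015039e-01 3.814287e-01
25.500 3.896624e-01 3.701793e-01
26.000 3.784436e-01 3.595214e-01
26.500 3.678030e-01 3.494128e-01
27.000 3.577000e-01 3.398150e-01
27.500 3.480977e-01 3.306929e-01
28.000 3.389623e-01 3.220142e-01
28.500 3.302629e-01 3.137498e-01
29.000 3.219711e-01 3.058725e-01
29.500 3.140608e-01 2.983577e-01
30.000 3.065080e-01 2.911826e-01
30.500 3.020733e-01 2.869696e-01
31.000 2.977893e-01 2.828999e-01
31.500 2.936485e-01 2.789661e-01
32.000 2.896437e-01 2.751615e-01
32.500 2.857682e-01 2.714798e-01
33.000 2.820158e-01 2.679150e-01
33.500 2.783806e-01 2.644616e-01
34.000 2.748572e-01 2.611143e-01
34.500 2.714403e-01 2.578683e-01
35.000 2.681253e-01 2.547190e-01
35.500 2.649074e-01 2.516620e-01
36.000 2.617825e-01 2.486934e-01
36.500 2.587465e-01 2.458092e-01
37.000 2.557957e-01 2.430059e-01
37.500 2.529264e-01 2.402800e-01
38.000 2.501352e-01 2.376284e-01
38.500 2.474190e-01 2.350480e-01
39.000 2.447747e-01 2.325360e-01
39.500 2.421995e-01 2.300895e-01
40.000 2.396906e-01 2.277061e-01
40.500 2.380613e-01 2.261582e-01
41.000 2.364660e-01 2.246427e-01
41.500 2.349036e-01 2.231584e-01
42.000 2.333730e-01 2.217043e-01
42.500 2.318731e-01 2.202794e-01
43.000 2.304029e-01 2.188828e-01
43.500 2.289616e-01 2.175135e-01
44.000 2.275482e-01 2.161707e-01
44.500 2.261617e-01 2.148536e-01
45.000 2.248015e-01 2.135614e-01
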