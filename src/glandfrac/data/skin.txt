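energy_keV mu_over_rho_cm2_g mu_per_cm  # material=skin density_g_cm3=1.09
10.000 4.952990e+00 5.398759e+00
10.500 4.309768e+00 4.697647e+00
11.000 3.775060e+00 4.114815e+00
11.500 3.326796e+00 3.626207e+00
12.000 2.948098e+00 3.213427e+00
12.500 2.625907e+00 2.862238e+00
13.000 2.350007e+00 2.561507e+00
13.500 2.112328e+00 2.302438e+00
14.000 1.906439e+00 2.078018e+00
14.500 1.727166e+00 1.882611e+00
15.000 1.570320e+00 1.711649e+00
15.500 1.446216e+00 1.576375e+00
16.000 1.335670e+00 1.455880e+00
16.500 1.236841e+00 1.348157e+00
17.000 1.148183e+00 1.251520e+00
17.500 1.068393e+00 1.164548e+00
18.000 9.963638e-01 1.086037e+00
18.500 9.311540e-01 1.014958e+00
19.000 8.719571e-01 9.504332e-01
19.500 8.180801e-01 8.917073e-01
20.000 7.689251e-01 8.381284e-01
20.500 7.334807e-01 7.994939e-01
21.000 7.005819e-01 7.636342e-01
21.500 6.699895e-01 7.302885e-01
22.000 6.414918e-01 6.992261e-01
22.500 6.149009e-01 6.702420e-01
23.000 5.900495e-01 6.431540e-01
23.500 5.667883e-01 6.177993e-01
24.000 5.449837e-01 5.940322e-01
24.500 5.245158e-01 5.717222e-01
25.000 5.052768e-01 5.507517e-01
25.500 4.871698e-01 5.310151e-01
26.000 4.701070e-01 5.124166e-01
26.500 4.540090e-01 4.948698e-01
27.000 4.388041e-01 4.782965e-01
27.500 4.244268e-01 4.626252e-01
28.000 4.108177e-01 4.477913e-01
28.500 3.979227e-01 4.337357e-01
29.000 3.856922e-01 4.204045e-01
29.500 3.740809e-01 4.077482e-01
30.000 3.630475e-01 3.957218e-01
30.500 3.561134e-01 3.881636e-01
31.000 3.494451e-01 3.808951e-01
31.500 3.430281e-01 3.739006e-01
32.000 3.368487e-01 3.671651e-01
32.500 3.308944e-01 3.606749e-01
33.000 3.251533e-01 3.544171e-01
33.500 3.196145e-01 3.483798e-01
34.000 3.142677e-01 3.425518e-01
34.500 3.091034e-01 3.369227e-01
35.000 3.041126e-01 3.314828e-01
35.500 2.992870e-01 3.262228e-01
36.000 2.946185e-01 3.211342e-01
36.500 2.901000e-01 3.162089e-01
37.000 2.857243e-01 3.114395e-01
37.500 2.814851e-01 3.068187e-01
38.000 2.773761e-01 3.023400e-01
38.500 2.733917e-01 2.979970e-01
39.000 2.695263e-01 2.937837e-01
39.500 2.657749e-01 2.896946e-01
40.000 2.621325e-01 2.857244e-01
40.500 2.597377e-01 2.831140e-01
41.000 2.573993e-01 2.805652e-01
41.500 2.551153e-01 2.780757e-01
42.000 2.528838e-01 2.756434e-01
42.500 2.507029e-01 2.732661e-01
43.000 2.485707e-01 2.709421e-01
43.500 2.464857e-01 2.686694e-01
44.000 2.444460e-01 2.664462e-01
44.500 2.424504e-01 2.642709e-01
45.000 2.404971e-01 2.621419e-01
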