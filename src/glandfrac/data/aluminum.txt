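energy_keV mu_over_rho_cm2_g mu_per_cm  # material=aluminum density_g_cm3=2.699
10.000 2.623000e+01 7.079477e+01
10.500 2.272206e+01 6.132683e+01
11.000 1.981518e+01 5.348118e+01
11.500 1.738568e+01 4.692394e+01
12.000 1.533922e+01 4.140054e+01
12.500 1.360302e+01 3.671455e+01
13.000 1.212031e+01 3.271272e+01
13.500 1.084636e+01 2.927433e+01
14.000 9.745600e+00 2.630338e+01
14.500 8.789500e+00 2.372286e+01
15.000 7.955000e+00 2.147055e+01
15.500 7.230307e+00 1.951460e+01
16.000 6.591595e+00 1.779071e+01
16.500 6.026433e+00 1.626534e+01
17.000 5.524493e+00 1.491061e+01
17.500 5.077143e+00 1.370321e+01
18.000 4.677131e+00 1.262358e+01
18.500 4.318334e+00 1.165518e+01
19.000 3.995558e+00 1.078401e+01
19.500 3.704376e+00 9.998110e+00
20.000 3.441000e+00 9.287259e+00
20.500 3.215041e+00 8.677394e+00
21.000 3.008840e+00 8.120859e+00
21.500 2.820260e+00 7.611882e+00
22.000 2.647436e+00 7.145430e+00
22.500 2.488737e+00 6.717102e+00
23.000 2.342732e+00 6.323034e+00
23.500 2.208162e+00 5.959830e+00
24.000 2.083916e+00 5.624489e+00
24.500 1.969011e+00 5.314360e+00
25.000 1.862574e+00 5.027087e+00
25.500 1.763831e+00 4.760580e+00
26.000 1.672091e+00 4.512973e+00
26.500 1.586735e+00 4.282599e+00
27.000 1.507213e+00 4.067967e+00
27.500 1.433027e+00 3.867740e+00
28.000 1.363732e+00 3.680714e+00
28.500 1.298928e+00 3.505806e+00
29.000 1.238250e+00 3.342038e+00
29.500 1.181373e+00 3.188527e+00
30.000 1.128000e+00 3.044472e+00
30.500 1.084454e+00 2.926942e+00
31.000 1.043257e+00 2.815750e+00
31.500 1.004247e+00 2.710462e+00
32.000 9.672759e-01 2.610678e+00
32.500 9.322080e-01 2.516029e+00
33.000 8.989182e-01 2.426180e+00
33.500 8.672912e-01 2.340819e+00
34.000 8.372212e-01 2.259660e+00
34.500 8.086102e-01 2.182439e+00
35.000 7.813677e-01 2.108912e+00
35.500 7.554103e-01 2.038852e+00
36.000 7.306603e-01 1.972052e+00
36.500 7.070460e-01 1.908317e+00
37.000 6.845008e-01 1.847468e+00
37.500 6.629628e-01 1.789337e+00
38.000 6.423745e-01 1.733769e+00
38.500 6.226823e-01 1.680620e+00
39.000 6.038363e-01 1.629754e+00
39.500 5.857900e-01 1.581047e+00
40.000 5.685000e-01 1.534381e+00
40.500 5.549091e-01 1.497700e+00
41.000 5.418039e-01 1.462329e+00
41.500 5.291616e-01 1.428207e+00
42.000 5.169603e-01 1.395276e+00
42.500 5.051799e-01 1.363481e+00
43.000 4.938010e-01 1.332769e+00
43.500 4.828056e-01 1.303092e+00
44.000 4.721765e-01 1.274404e+00
44.500 4.618976e-01 1.246662e+00
45.000 4.519536e-01 1.219823e+00
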