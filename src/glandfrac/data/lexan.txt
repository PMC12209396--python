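energy_keV mu_over_rho_cm2_g mu_per_cm  # material=lexan density_g_cm3=1.2
10.000 2.938403e+00 3.526084e+00
10.500 2.571795e+00 3.086154e+00
11.000 2.265294e+00 2.718353e+00
11.500 2.006939e+00 2.408327e+00
12.000 1.787533e+00 2.145040e+00
12.500 1.599924e+00 1.919909e+00
13.000 1.438491e+00 1.726189e+00
13.500 1.298771e+00 1.558525e+00
14.000 1.177192e+00 1.412630e+00
14.500 1.070868e+00 1.285042e+00
15.000 9.774525e-01 1.172943e+00
15.500 9.084611e-01 1.090153e+00
16.000 8.464527e-01 1.015743e+00
16.500 7.905302e-01 9.486362e-01
17.000 7.399348e-01 8.879217e-01
17.500 6.940211e-01 8.328254e-01
18.000 6.522378e-01 7.826853e-01
18.500 6.141113e-01 7.369336e-01
19.000 5.792336e-01 6.950803e-01
19.500 5.472514e-01 6.567016e-01
20.000 5.178575e-01 6.214290e-01
20.500 4.988697e-01 5.986436e-01
21.000 4.810644e-01 5.772773e-01
21.500 4.643412e-01 5.572095e-01
22.000 4.486104e-01 5.383325e-01
22.500 4.337915e-01 5.205498e-01
23.000 4.198123e-01 5.037747e-01
23.500 4.066075e-01 4.879291e-01
24.000 3.941186e-01 4.729423e-01
24.500 3.822923e-01 4.587508e-01
25.000 3.710804e-01 4.452965e-01
25.500 3.604392e-01 4.325270e-01
26.000 3.503286e-01 4.203944e-01
26.500 3.407125e-01 4.088550e-01
27.000 3.315574e-01 3.978689e-01
27.500 3.228331e-01 3.873998e-01
28.000 3.145117e-01 3.774140e-01
28.500 3.065674e-01 3.678809e-01
29.000 2.989768e-01 3.587721e-01
29.500 2.917181e-01 3.500617e-01
30.000 2.847714e-01 3.417256e-01
30.500 2.808694e-01 3.370433e-01
31.000 2.770907e-01 3.325089e-01
31.500 2.734293e-01 3.281152e-01
32.000 2.698798e-01 3.238558e-01
32.500 2.664369e-01 3.197243e-01
33.000 2.630959e-01 3.157151e-01
33.500 2.598521e-01 3.118226e-01
34.000 2.567014e-01 3.080417e-01
34.500 2.536396e-01 3.043675e-01
35.000 2.506629e-01 3.007955e-01
35.500 2.477679e-01 2.973214e-01
36.000 2.449510e-01 2.939412e-01
36.500 2.422090e-01 2.906509e-01
37.000 2.395391e-01 2.874469e-01
37.500 2.369382e-01 2.843259e-01
38.000 2.344037e-01 2.812845e-01
38.500 2.319330e-01 2.783197e-01
39.000 2.295237e-01 2.754285e-01
39.500 2.271734e-01 2.726081e-01
40.000 2.248800e-01 2.698560e-01
40.500 2.234216e-01 2.681060e-01
41.000 2.219918e-01 2.663902e-01
41.500 2.205896e-01 2.647075e-01
42.000 2.192141e-01 2.630569e-01
42.500 2.178646e-01 2.614375e-01
43.000 2.165402e-01 2.598482e-01
43.500 2.152402e-01 2.582882e-01
44.000 2.139638e-01 2.567566e-01
44.500 2.127104e-01 2.552525e-01
45.000 2.114793e-01 2.537752e-01
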