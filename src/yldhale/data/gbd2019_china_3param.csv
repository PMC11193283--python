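age_group,sex,beta,a,b,c,beta_lo,beta_hi,a_lo,a_hi,b_lo,b_hi,c_lo,c_hi
0,male,1.8615,8.9296,0.0749,-3.4638,1.5676,2.1686,-89.86,104.4651,-0.3495,0.5163,-6.2056,-0.6767
0,female,1.9244,1.4015,-0.0339,-4.0875,1.6017,2.2606,-89.2012,98.5111,-0.5089,0.4189,-6.7341,-0.9566
0,both,1.8893,5.0838,0.0277,-3.7456,1.5782,2.2044,-95.0983,98.3153,-0.3935,0.4767,-6.4152,-0.8885
1-4,male,1.9694,-5.1199,-0.2137,-2.7403,1.6564,2.282,-105.66,89.3598,-0.6211,0.2179,-5.311,0.1668
1-4,female,2.0788,-9.8239,-0.3049,-3.5109,1.7471,2.4175,-103.8426,90.4263,-0.7628,0.1747,-6.3764,-0.5827
1-4,both,2.0151,-6.7746,-0.2498,-3.0582,1.6647,2.3346,-108.6964,93.8619,-0.6564,0.2006,-5.7274,-0.1229
5-9,male,1.8413,-0.8975,-0.1547,-1.9308,1.525,2.1515,-101.7561,94.1937,-0.569,0.2849,-4.5082,1.0019
5-9,female,1.9073,-0.0878,-0.1897,-2.339,1.5992,2.2224,-89.1423,95.2822,-0.6449,0.2733,-5.0928,0.4604
5-9,both,1.8688,-0.1318,-0.1682,-2.0884,1.5419,2.19,-97.964,99.0181,-0.5808,0.2811,-4.6995,0.8061
10-14,male,1.6316,1.9377,-0.0537,-0.8173,1.3374,1.9374,-97.2023,95.3694,-0.4723,0.3893,-3.4299,2.0455
10-14,female,1.5875,1.5146,-0.0599,-0.7935,1.2654,1.9069,-83.0149,99.3105,-0.5111,0.391,-3.4908,1.9591
10-14,both,1.6099,1.9764,-0.0552,-0.8259,1.2935,1.9257,-90.8264,97.9303,-0.4808,0.3775,-3.3644,1.7507
15-19,male,1.5261,3.794,-0.0335,-0.6617,1.2449,1.8354,-93.8766,94.1744,-0.4508,0.3749,-3.3066,2.0369
15-19,female,1.4563,-1.4657,-0.0635,-1.2921,1.1364,1.7867,-92.6654,94.5287,-0.5362,0.4028,-4.0064,1.5633
15-19,both,1.4898,0.9114,-0.042,-1.0058,1.171,1.7968,-91.2431,95.0335,-0.4779,0.4019,-3.4936,1.5461
20-24,male,1.4536,4.2732,-0.0374,-1.227,1.1914,1.738,-82.274,88.3974,-0.4256,0.3432,-3.6582,1.2982
20-24,female,1.3738,-2.7204,-0.0654,-2.0357,1.0737,1.6944,-89.8365,88.28,-0.5239,0.3675,-4.5894,0.7386
20-24,both,1.4092,0.269,-0.042,-1.6123,1.115,1.698,-86.5912,85.2794,-0.4448,0.3843,-4.0458,0.7989
25-29,male,1.3981,-0.693,-0.071,-1.2683,1.145,1.6852,-92.0414,85.5352,-0.4481,0.3159,-3.7395,1.239
25-29,female,1.2745,-3.5984,-0.0426,-1.9072,0.9582,1.6023,-95.8204,89.5813,-0.5183,0.4044,-4.5349,1.0659
25-29,both,1.334,-3.0808,-0.0532,-1.5637,1.0227,1.6283,-92.6824,84.617,-0.4668,0.3865,-4.0372,0.9158
30-34,male,1.355,-3.8105,-0.0995,-1.2241,1.0825,1.6537,-99.3002,86.6227,-0.5006,0.292,-3.7556,1.476
30-34,female,1.1988,-3.6009,-0.0307,-1.7896,0.8692,1.5326,-98.9042,89.4311,-0.5154,0.4211,-4.459,1.2694
30-34,both,1.2725,-3.3793,-0.0623,-1.4924,0.9508,1.5746,-97.621,90.2346,-0.489,0.3835,-4.0047,1.1893
35-39,male,1.3017,-4.8401,-0.1094,-1.2015,1.0351,1.5927,-99.3466,81.1911,-0.4948,0.2805,-3.6518,1.3679
35-39,female,1.1471,-5.9297,-0.0362,-1.722,0.8328,1.4698,-98.9376,87.4883,-0.5058,0.4076,-4.3229,1.2322
35-39,both,1.2219,-5.4039,-0.0707,-1.4605,0.9178,1.5141,-94.3819,84.6567,-0.4856,0.3752,-3.9564,1.1055
40-44,male,1.2235,-3.9177,-0.1054,-0.9989,0.9435,1.5236,-98.8668,84.7891,-0.4978,0.3085,-3.4551,1.6916
40-44,female,1.0765,-6.3659,-0.0302,-1.429,0.7607,1.4012,-101.6396,87.6795,-0.5097,0.4269,-4.0477,1.5179
40-44,both,1.147,-4.9543,-0.0656,-1.1952,0.8339,1.4453,-98.126,85.1809,-0.4943,0.3699,-3.738,1.4064
45-49,male,1.147,-4.3704,-0.0855,-0.8279,0.8608,1.4537,-101.06,85.1792,-0.4893,0.3345,-3.3536,1.938
45-49,female,1.0049,-5.081,-0.0269,-1.1509,0.6872,1.3301,-99.3075,88.5691,-0.5162,0.4319,-3.7588,1.7713
45-49,both,1.0716,-3.9819,-0.0542,-0.9499,0.7573,1.3766,-98.1502,89.3272,-0.4911,0.4001,-3.5559,1.6995
50-54,male,1.064,-5.0987,-0.0629,-0.6543,0.7779,1.3822,-101.6711,86.558,-0.4766,0.3672,-3.2642,2.1167
50-54,female,0.9263,-5.3515,-0.0176,-0.9582,0.6099,1.2474,-98.0374,89.4413,-0.5021,0.4305,-3.5471,1.9832
50-54,both,0.9918,-4.8706,-0.0399,-0.7512,0.6765,1.2982,-101.1156,87.1881,-0.4833,0.4161,-3.3769,1.9276
55-59,male,0.9734,-6.1668,-0.0428,-0.5263,0.6885,1.2923,-100.2057,90.1042,-0.458,0.3824,-3.1987,2.1742
55-59,female,0.855,-7.3568,-0.0097,-0.7126,0.5407,1.1749,-103.2215,83.4189,-0.4922,0.4641,-3.3674,2.1542
55-59,both,0.9136,-7.0781,-0.0272,-0.5775,0.5897,1.2317,-101.4935,83.6403,-0.4707,0.4594,-3.2193,2.072
60-64,male,0.8716,-7.2787,-0.0142,-0.3027,0.5849,1.1754,-103.3529,89.184,-0.4208,0.416,-2.9157,2.3396
60-64,female,0.768,-8.392,0.0077,-0.4027,0.4397,1.0843,-103.148,87.0003,-0.4696,0.4859,-3.0952,2.5065
60-64,both,0.8216,-8.2262,-0.0086,-0.3444,0.5069,1.1228,-100.3827,80.3776,-0.4604,0.4812,-3.0742,2.4549
65-69,male,0.7501,-7.0827,0.0298,-0.1241,0.4676,1.0324,-95.9519,79.0654,-0.3817,0.4741,-2.8241,2.5645
65-69,female,0.662,-7.7256,0.0263,-0.2158,0.3442,0.9885,-101.1817,90.0398,-0.4443,0.4832,-2.9427,2.6614
65-69,both,0.7091,-7.7619,0.0199,-0.2119,0.4118,1.001,-94.8636,77.8574,-0.4051,0.4821,-2.8057,2.4425
70-74,male,0.6373,-6.3963,0.0507,0.0401,0.3512,0.9403,-97.9173,82.0546,-0.346,0.4975,-2.8468,2.8818
70-74,female,0.5604,-6.6255,0.0292,-0.071,0.2521,0.8764,-97.2704,91.4211,-0.4452,0.4706,-2.7701,2.7855
70-74,both,0.6016,-6.9564,0.033,-0.0923,0.3059,0.9141,-99.3681,76.6746,-0.3856,0.4962,-2.7044,2.6144
75-79,male,0.5494,-5.3748,0.0363,0.2235,0.2213,0.8751,-105.2794,88.8814,-0.4093,0.4931,-2.8412,3.175
75-79,female,0.4713,-5.555,0.0143,0.0803,0.1574,0.7996,-101.808,90.0585,-0.4464,0.4868,-2.7465,2.8094
75-79,both,0.5094,-5.5586,0.0228,0.0533,0.1977,0.8408,-97.4039,87.087,-0.4503,0.4946,-2.5135,2.9136
80-84,male,0.4613,-3.388,0.0117,0.4306,0.1199,0.7939,-101.8622,102.616,-0.4504,0.4671,-2.4492,3.3016
80-84,female,0.3734,-2.7735,-0.0082,0.2355,0.0518,0.6938,-95.5256,93.9542,-0.4921,0.4961,-2.7983,3.0682
80-84,both,0.4092,-2.8768,0.0049,0.237,0.0962,0.7623,-99.8572,93.4903,-0.4803,0.4952,-2.6374,3.2957
85-89,male,0.3952,-0.6385,-0.0151,0.4766,0.0485,0.7345,-102.0297,112.085,-0.4789,0.4497,-2.5766,3.5764
85-89,female,0.3067,1.377,-0.0421,0.0682,-0.0217,0.6456,-99.3191,99.616,-0.5589,0.4754,-2.9729,3.0247
85-89,both,0.3354,0.0632,-0.0277,0.1716,0.0222,0.6869,-100.3999,98.5852,-0.5356,0.4512,-3.0417,3.2445
90-94,male,0.3365,3.5145,-0.0338,0.6014,-0.0128,0.6713,-96.6604,114.9733,-0.5164,0.4335,-2.3655,3.638
90-94,female,0.2523,6.5459,-0.0812,-0.1256,-0.0798,0.5816,-87.0686,108.0101,-0.615,0.4209,-3.2322,2.9552
90-94,both,0.2702,5.1485,-0.0843,0.0399,-0.0434,0.5961,-93.6325,106.3527,-0.5841,0.3881,-3.0837,3.047
95+,male,0.263,8.7173,-0.0469,0.6455,-0.0767,0.5999,-92.0022,121.9523,-0.5513,0.4205,-2.3148,3.64
95+,female,0.1828,12.5105,-0.1043,-0.3791,-0.1644,0.5225,-86.6712,113.2924,-0.6223,0.3976,-3.5573,2.5804
95+,both,0.1937,12.2797,-0.1106,-0.2437,-0.1699,0.5055,-87.3525,121.4148,-0.6319,0.3815,-3.0914,2.9493
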