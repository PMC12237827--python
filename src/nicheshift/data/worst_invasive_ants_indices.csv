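species,tpsr,nbr,nsi,nc_test,rri,rsi,rc_test,br_lt_rr,nsi_gt_rsi
Acromyrmex octospinosus,0.063,0.522,0.686,Y,0.022,0.000,Y,N,Y
Anoplolepis gracilipes,0.997,0.925,0.923,Y,0.495,0.285,Y,N,Y
Lasius neglectus,4.632,1.995,0.225,N,3.462,0.003,N,Y,Y
Linepithema humile,1.745,1.271,0.864,Y,4.543,0.080,N,Y,Y
Monomorium floricola,2.406,0.955,0.952,Y,4.248,0.238,N,Y,Y
Monomorium pharaonic,3.531,2.290,0.608,Y,7.837,0.030,N,Y,Y
Myrmica rubra,0.756,0.798,0.876,Y,0.269,0.010,Y,N,Y
Pachycondyla chinensis,1.171,0.715,0.831,Y,1.289,0.000,N,Y,Y
Paratrechina longicornis,1.579,1.068,0.896,Y,4.490,0.038,N,Y,Y
Pheidole megacephala,1.604,1.355,0.834,Y,1.908,0.122,N,Y,Y
Solenopsis geminata,0.956,1.060,0.956,Y,0.540,0.256,Y,N,Y
Solenopsis invicta,1.663,1.013,0.932,Y,1.539,0.244,N,Y,Y
Solenopsis papuana,0.738,0.619,0.752,Y,0.308,0.024,Y,N,Y
Solenopsis richteri,0.635,0.705,0.802,Y,0.835,0.022,Y,Y,Y
Tapinoma melanocephalum,2.169,1.088,0.938,Y,3.481,0.214,N,Y,Y
Technomyrmex albipes,2.199,1.112,0.917,Y,2.879,0.176,N,Y,Y
Trichomyrmex destructor,1.498,1.245,0.847,Y,2.582,0.039,N,Y,Y
Wasmannia auropunctata,1.642,0.909,0.949,Y,0.537,0.285,Y,N,Y
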