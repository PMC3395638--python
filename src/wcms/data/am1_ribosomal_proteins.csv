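locus_tag,gene,subunit,length,second_aa,met_loss,theoretical_mass,wcms_mz,wcms_error,ribosome_mz,ribosome_error,remark
2938,rpmJ,L36,41,K,no,4994.94,4993.07,-1.87,4993.95,-0.99,
2356,rpmH,L34,44,K,no,5090.12,5088.29,-1.83,5089.62,-0.50,
1700,rpmG,L33,55,A,yes,6264.60,,,6278.49,13.89,Methylated
3696,rpmF,L32,62,A,yes,6905.14,6904.83,-0.32,6905.05,-0.10,
2174,rpmD,L30,64,A,yes,6943.34,6943.58,0.24,6943.05,-0.28,
1521,rpmI,L35,67,P,yes,7481.02,7481.77,0.75,7481.37,0.35,
2161,rpmC,L29,71,K,no,8155.33,8156.32,0.98,8156.14,0.81,
2358,rpmE,L31,84,A,yes,9119.34,9119.97,0.63,9119.99,0.65,
4323,rpsR,S18,84,A,yes,9211.99,9208.78,-3.22,9208.06,-3.94,Acetylated 9254.00 was not observed
4855,rpmA,L27,88,A,yes,9335.88,,,,,
5345,rpsT,S20,88,A,yes,9528.32,9530.89,2.57,9529.65,1.33,
2162,rpsQ,S17,88,P,yes,9692.29,9692.72,0.44,9693.75,1.46,
4417,rpsO,S15,89,S,yes,10216.97,10218.78,1.81,10218.91,1.94,
2157,rpsS,S19,92,A,no,10231.98,,,,,
2155,rplW,L23,98,S,yes,10711.55,,,10713.03,1.48,
2181,rplX,L24,104,A,yes,11084.87,11089.45,4.58,11085.95,1.08,
3182,rpmB,L28,101,S,no,11209.24,11206.90,-2.34,11210.13,0.89,
2179,rpsN,S14,101,A,no,11595.65,11597.20,1.55,11597.25,1.60,
2152,rpsJ,S10,102,N,no,11607.53,,,,,
4149,rpsU,S21,105,Q,no,11667.77,11667.86,0.09,11669.52,1.75,
4404,rplL,L7/L12,125,A,yes,12617.74,12616.89,-0.85,,,
2176,rplR,L18,120,S,yes,12682.74,,,12684.87,2.13,
479,rpsP,S16,120,S,yes,13078.22,13079.70,1.48,13080.20,1.98,
2182,rplN,L14,122,I,no,13347.90,,,,,
1522,rplT,L20,121,A,yes,13496.96,13500.01,3.06,13499.52,2.57,
2148,rpsL,S12,123,P,yes,13675.27,,,13719.69,44.42,Beta-methylthiolated
2170,rpsM,S13,122,A,yes,13715.28,13716.81,1.53,,,
2169,rpsK,S11,129,A,yes,13735.72,,,,,
2158,rplV,L22,127,G,yes,13788.35,,,,,
4856,rplU,L21,130,F,no,13904.88,,,,,
2178,rpsH,S8,131,V,yes,14497.78,,,,,
5186,rplS,L19,134,N,no,15059.31,,,,,
2160,rplP,L16,137,L,no,15458.22,,,,,
2166,rplQ,L17,138,R,no,15535.06,,,15537.36,2.30,
4385,rplK,L11,149,A,yes,15643.71,,,,,
2177,rplF,L6,154,K,no,16859.58,,,,,
4324,rpsF,S6,148,P,yes,16898.14,,,,,
2739,rplM,L13,153,K,no,17174.02,,,17172.30,-1.72,
2173,rplO,L15,169,K,no,17367.89,,,,,
4403,rplJ,L10,172,D,no,17666.73,,,,,
2149,rpsG,S7,156,S,yes,17798.47,,,,,
2740,rpsI,S9,163,I,no,18311.14,,,,,
2175,rpsE,S5,192,A,yes,20678.70,,,,,
4321,rplL,L9,190,E,no,20949.59,,,,,
2180,rplE,L5,188,A,yes,21104.74,,,,,
2154,rplD,L4,206,K,no,22517.00,,,,,
5190,rpsD,S4,205,S,yes,23572.29,,,,,
2440,rplY,L25,228,S,yes,23718.79,,,,,
4386,rplA,L1,232,A,yes,24172.39,,,,,
2153,rplC,L3,246,R,no,26108.92,,,,,
2159,rpsC,S3,248,G,yes,27531.97,,,,,
2156,rplB,L2,278,A,yes,30095.72,,,,,
2057,rpsB,S2,349,R,no,37455.57,,,,,
55,rpsA,S1,570,S,yes,62790.44,,,,,
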