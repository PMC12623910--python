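# Element parameters for X-ray data reduction.
# Z: atomic number; weight: standard atomic weight (g/mol).
# a1-a4, b1-b4, c: Cromer-Mann coefficients for the coherent atomic form
#   factor f(s) = sum_j a_j exp(-b_j s^2) + c with s = Q/(4 pi) (International
#   Tables for Crystallography Vol. C parameterisation, neutral atoms).
# incoh_k, incoh_p: coefficients of the two-parameter incoherent (Compton)
#   saturation model I_inc(Q) = (Z - f(Q)^2/Z) * (1 - exp(-incoh_k * Q**incoh_p)).
symbol,Z,weight,a1,a2,a3,a4,b1,b2,b3,b4,c,incoh_k,incoh_p
H,1,1.008,0.489918,0.262003,0.196767,0.049879,20.6593,7.74039,49.5519,2.20159,0.001305,0.60,1.4
C,6,12.011,2.31000,1.02000,1.58860,0.865000,20.8439,10.2075,0.568700,51.6512,0.215600,0.28,1.4
N,7,14.007,12.2126,3.13220,2.01250,1.16630,0.005700,9.89330,28.9975,0.582600,-11.529,0.26,1.4
O,8,15.999,3.04850,2.28680,1.54630,0.867000,13.2771,5.70110,0.323900,32.9089,0.250800,0.24,1.4
P,15,30.974,6.43450,4.17910,1.78000,1.49080,1.90670,27.1570,0.526000,68.1645,1.11490,0.16,1.4
S,16,32.06,6.90530,5.20340,1.43790,1.58630,1.46790,22.2151,0.253600,56.1720,0.866900,0.155,1.4
Cl,17,35.45,11.4604,7.19640,6.25560,1.64550,0.010400,1.16620,18.5194,47.7784,-9.5574,0.15,1.4
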