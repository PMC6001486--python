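# Magnetic nuclide constants for NMR work.
# gamma: gyromagnetic ratio in rad s^-1 T^-1, signed (negative = precession
#        in the positive sense at positive field); values follow the
#        IAEA-recommended / CODATA-derived compilations commonly used in NMR
#        (Harris et al., Pure Appl. Chem. 73, 1795 (2001) conventions).
# spin: spin quantum number; abundance: natural abundance in percent.
isotope,spin,gamma,abundance
1H,0.5,2.6752218744e8,99.9885
2H,1.0,4.10662791e7,0.0115
3He,0.5,-2.03801587e8,0.000134
6Li,1.0,3.9371709e7,7.59
7Li,1.5,1.03977013e8,92.41
11B,1.5,8.5847044e7,80.1
13C,0.5,6.728284e7,1.07
14N,1.0,1.9337792e7,99.636
15N,0.5,-2.71261804e7,0.364
17O,2.5,-3.62808e7,0.038
19F,0.5,2.518148e8,100.0
23Na,1.5,7.0808493e7,100.0
27Al,2.5,6.9762715e7,100.0
29Si,0.5,-5.3190e7,4.685
31P,0.5,1.08394e8,100.0
35Cl,1.5,2.624198e7,75.76
79Br,1.5,6.725616e7,50.69
109Ag,0.5,-1.2518634e7,48.161
119Sn,0.5,-1.0031727e8,8.59
129Xe,0.5,-7.452103e7,26.401
195Pt,0.5,5.8385e7,33.775
207Pb,0.5,5.58046e7,22.1
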