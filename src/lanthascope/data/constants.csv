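name,kind,charge,logk25,delta_h_kj_mol,H,Na,K,Cl,Mg,Ca,SO4,CO3,PO4,La,source
H+,basis,1,0,,1,0,0,0,0,0,0,0,0,0,basis
Na+,basis,1,0,,0,1,0,0,0,0,0,0,0,0,basis
K+,basis,1,0,,0,0,1,0,0,0,0,0,0,0,basis
Cl-,basis,-1,0,,0,0,0,1,0,0,0,0,0,0,basis
Mg+2,basis,2,0,,0,0,0,0,1,0,0,0,0,0,basis
Ca+2,basis,2,0,,0,0,0,0,0,1,0,0,0,0,basis
SO4-2,basis,-2,0,,0,0,0,0,0,0,1,0,0,0,basis
CO3-2,basis,-2,0,,0,0,0,0,0,0,0,1,0,0,basis
PO4-3,basis,-3,0,,0,0,0,0,0,0,0,0,1,0,basis
La+3,basis,3,0,,0,0,0,0,0,0,0,0,0,1,basis
OH-,aqueous,-1,-13.995,55.81,-1,0,0,0,0,0,0,0,0,0,CODATA water dissociation
CO2(aq),aqueous,0,16.681,-24.01,2,0,0,0,0,0,0,1,0,0,PHREEQC carbonate pK1+pK2
HCO3-,aqueous,-1,10.329,-14.90,1,0,0,0,0,0,0,1,0,0,PHREEQC carbonate pK2
H3PO4,aqueous,0,21.70,-10.3,3,0,0,0,0,0,0,0,1,0,NIST phosphoric acid cumulative
H2PO4-,aqueous,-1,19.55,-18.3,2,0,0,0,0,0,0,0,1,0,NIST phosphoric acid cumulative
HPO4-2,aqueous,-2,12.35,-14.7,1,0,0,0,0,0,0,0,1,0,NIST phosphoric acid pK3
LaOH+2,aqueous,2,-8.81,,-1,0,0,0,0,0,0,0,0,1,Klungness & Byrne 2000
LaCO3+,aqueous,1,7.00,,0,0,0,0,0,0,0,1,0,1,LLNL/SUPCRT REE set (Haas Shock & Sassani 1995)
La(CO3)2-,aqueous,-1,12.00,,0,0,0,0,0,0,0,2,0,1,LLNL/SUPCRT REE set (Haas Shock & Sassani 1995)
LaHCO3+2,aqueous,2,12.20,,1,0,0,0,0,0,0,1,0,1,Luo & Byrne 2004 bicarbonate step
LaSO4+,aqueous,1,3.62,,0,0,0,0,0,0,1,0,0,1,Schijf & Byrne 2004
MgCO3,aqueous,0,2.98,11.35,0,0,0,0,1,0,0,1,0,0,PHREEQC ion pair
CaCO3,aqueous,0,3.22,14.83,0,0,0,0,0,1,0,1,0,0,PHREEQC ion pair
MgSO4,aqueous,0,2.37,19.04,0,0,0,0,1,0,1,0,0,0,PHREEQC ion pair
CaSO4,aqueous,0,2.30,6.90,0,0,0,0,0,1,1,0,0,0,PHREEQC ion pair
NaSO4-,aqueous,-1,0.70,4.69,0,1,0,0,0,0,1,0,0,0,PHREEQC ion pair
LaPO4(s),mineral,0,-25.7,,0,0,0,0,0,0,0,0,1,1,Liu & Byrne 1997 rhabdophane
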