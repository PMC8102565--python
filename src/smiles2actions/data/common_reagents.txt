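# Compound names allowed to appear verbatim in action sequences even when
# the molecule is absent from the chemical equation.  One name per line;
# matching happens on the normalized form.  User-replaceable.
water
ice
ice water
brine
ethanol
methanol
isopropanol
THF
tetrahydrofuran
DMSO
dimethyl sulfoxide
DMF
dichloromethane
DCM
chloroform
ethyl acetate
EtOAc
diethyl ether
ether
hexane
hexanes
heptane
pentane
petroleum ether
toluene
acetone
acetonitrile
Na2SO4
sodium sulfate
MgSO4
magnesium sulfate
NaHCO3
sodium bicarbonate
sodium carbonate
K2CO3
potassium carbonate
NaCl
sodium chloride
ammonium chloride
NH4Cl
HCl
hydrochloric acid
NaOH
sodium hydroxide
celite
silica gel
nitrogen
argon
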