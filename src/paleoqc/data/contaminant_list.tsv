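# Default laboratory-contaminant target list for risk assessment and for
# contaminant spiking in the simulator. Synthetic stand-in for a molecular
# contaminant monitoring list; names cover the reagent classes commonly
# monitored in bottom-up proteomics.
name	contaminant_class
Polyethylene_glycol	polymer
Triton_X100	surfactant
Tween_20	surfactant
IGEPAL_CA630	surfactant
Sodium_dodecyl_sulfate	surfactant
Trypsin_porcine	enzyme
Keratin_K1	keratin
Keratin_K10	keratin
Serum_albumin_bovine	albumin
Polysiloxane	polymer
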