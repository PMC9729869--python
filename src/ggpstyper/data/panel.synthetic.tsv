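# synthetic typed reference panel; replace with curated homologs for real calls
SYNREF_I_archaeal_a	I
SYNREF_I_archaeal_b	I
SYNREF_II_plant_a	II
SYNREF_II_bacterial_a	II
SYNREF_III_fungal_a	III
SYNREF_III_fungal_b	III
SYNREF_III_animal_a	III
SYNREF_III_animal_b	III
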