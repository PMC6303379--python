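# drought-sensitive cultivar: carbon acts through the root-shoot ratio
root_shoot_ratio <- carbon_score
d_infiltration <- carbon_score
d_porosity <- root_shoot_ratio
d_respiration <- root_shoot_ratio
d_infiltration <- rhizosheath_mass
d_infiltration <- root_shoot_ratio
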