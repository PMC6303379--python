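# drought-tolerant cultivar: carbon builds the rhizosheath, root hairs act on habitat
rhizosheath_mass <- carbon_score
d_connectivity <- rhizosheath_mass
d_connectivity <- carbon_score
d_porosity <- carbon_score
d_porosity <- root_hair_area
d_connectivity <- root_hair_area
d_infiltration <- root_hair_area
d_respiration <- root_shoot_ratio
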