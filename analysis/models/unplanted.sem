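# unplanted control: carbon feeds the microbes, habitat unchanged
d_respiration <- carbon_score
d_porosity <- carbon_score
d_infiltration <- carbon_score
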