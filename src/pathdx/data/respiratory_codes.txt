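# curated group ids defining chronic respiratory conditions
copd_dx
asthma_dx
bronchiectasis_dx
pulmonary_fibrosis_dx
resp_infection_dx
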