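# curated group ids defining a lung cancer diagnosis
lung_cancer_dx
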