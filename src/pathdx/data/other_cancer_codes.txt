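# curated group ids defining non-lung cancer diagnoses
breast_cancer_dx
colorectal_cancer_dx
prostate_cancer_dx
gastric_cancer_dx
renal_cancer_dx
blood_cancer_dx
skin_cancer_dx
pancreatic_cancer_dx
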