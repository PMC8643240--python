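method,n_cancer,n_hyperplasia
pathology,39,50
mri_before,30,59
mri_after,37,52
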