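method,low,medium,high
pathology,14,17,8
mri_before,20,9,10
mri_after,15,16,8
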