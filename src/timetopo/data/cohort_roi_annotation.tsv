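label	n_rois
diffuse	35
focal	30
insignificant	37
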