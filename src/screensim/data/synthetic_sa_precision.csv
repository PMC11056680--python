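quantity,value
sa_screened,5791
matched_includes,0
precision_lower,0.55
precision_upper,0.72
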