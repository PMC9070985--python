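subject_id,g_mean,g_sd,tract_length_mm
S01,0.69,0.03,155.03
S02,0.71,0.03,149.38
S03,0.71,0.04,133.43
S04,0.69,0.04,136.25
S05,0.67,0.04,154.32
S06,0.69,0.03,171.41
S07,0.71,0.04,157.94
S08,0.71,0.03,149.95
S09,0.69,0.04,152.98
S10,0.68,0.03,142.29
S11,0.68,0.04,155.49
S12,0.69,0.03,172.32
S13,0.69,0.03,184.48
S14,0.69,0.04,154.40
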