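name: SI_fb
ka: 0.5
kd: 100.0
CA: 1.0
CF: 1.0
CS: 10.0
concentration_uM: 30.0
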