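{
 "wall": "lateral",
 "reference_A": 9.24,
 "reference_B": 6.8,
 "version": "mean-v1"
}
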